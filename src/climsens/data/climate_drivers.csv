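name,code,driver_class
climate change,CC,primary
oscillations,O,primary
extreme weather events,EWE,primary
moisture,M,primary
rainfall,R,primary
temperature,T,primary
wind,W,primary
altitude,Alt,secondary
vegetation,V,secondary
particulate matter,P,secondary
salinity,S,secondary
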