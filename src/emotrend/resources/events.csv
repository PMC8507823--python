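week,label
7,US public health emergency declared
10,Cruise ship outbreak reported
11,WHO pandemic declaration; US national emergency
18,Antiviral emergency use authorization
24,US reaches 2 million cases
27,Projection of 100000 cases per day
30,Promising vaccine and treatment reports
44,Vaccine coverage rules; European lockdowns
45,US election day
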