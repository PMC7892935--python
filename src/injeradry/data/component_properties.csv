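component,property,order,coefficient
water,density,0,997.18
water,density,1,3.1439e-3
water,density,2,-3.7574e-3
carbohydrate,density,0,1599.1
carbohydrate,density,1,-0.31046
protein,density,0,1329.9
protein,density,1,-0.5184
fat,density,0,925.59
fat,density,1,-0.41757
fiber,density,0,1311.5
fiber,density,1,-0.36589
ash,density,0,2423.8
ash,density,1,-0.28063
water,specific_heat,0,4176.2
water,specific_heat,1,-0.0909
water,specific_heat,2,5.4731e-3
carbohydrate,specific_heat,0,1548.8
carbohydrate,specific_heat,1,1.9625
carbohydrate,specific_heat,2,-5.9399e-3
protein,specific_heat,0,2008.2
protein,specific_heat,1,1.2089
protein,specific_heat,2,-1.3129e-3
fat,specific_heat,0,1984.2
fat,specific_heat,1,1.4733
fat,specific_heat,2,-4.8008e-3
fiber,specific_heat,0,1845.9
fiber,specific_heat,1,1.8306
fiber,specific_heat,2,-4.6509e-3
ash,specific_heat,0,1092.6
ash,specific_heat,1,1.8896
ash,specific_heat,2,-3.6817e-3
water,conductivity,0,0.57109
water,conductivity,1,1.7625e-3
water,conductivity,2,-6.7036e-6
carbohydrate,conductivity,0,0.20141
carbohydrate,conductivity,1,1.3874e-3
carbohydrate,conductivity,2,-4.3312e-6
protein,conductivity,0,0.17881
protein,conductivity,1,1.1958e-3
protein,conductivity,2,-2.7178e-6
fat,conductivity,0,0.18071
fat,conductivity,1,-2.7604e-4
fat,conductivity,2,-1.7749e-7
fiber,conductivity,0,0.18331
fiber,conductivity,1,1.2497e-3
fiber,conductivity,2,-3.1683e-6
ash,conductivity,0,0.32962
ash,conductivity,1,1.4011e-3
ash,conductivity,2,-2.9069e-6
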