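metric,hqsar,comfa,comsia,topomer
r2_pred,0.814,0.829,0.758,0.855
k,0.977,0.980,0.978,0.984
k_prime,1.018,1.015,1.017,1.012
r0_sq,0.828,0.838,0.803,0.860
r0_sq_prime,0.807,0.779,0.770,0.836
rm_sq,0.610,0.609,0.559,0.647
rm_sq_prime,0.584,0.539,0.523,0.615
delta_rm_sq,0.026,0.070,0.036,0.033
rmse,0.501,0.480,0.530,0.443
mae,0.543,0.547,0.565,0.462
ccc,0.902,0.902,0.888,0.922
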