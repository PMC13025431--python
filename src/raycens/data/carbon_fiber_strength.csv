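strength
0.562
0.564
0.729
0.802
0.950
1.053
1.111
1.115
1.194
1.208
1.216
1.247
1.256
1.271
1.277
1.305
1.313
1.348
1.390
1.429
1.474
1.490
1.503
1.520
1.522
1.524
1.551
1.551
1.609
1.632
1.632
1.676
1.684
1.685
1.728
1.740
1.761
1.764
1.785
1.804
1.816
1.824
1.836
1.879
1.883
1.892
1.898
1.934
1.947
1.976
2.020
2.023
2.050
2.059
2.068
2.071
2.098
2.130
2.204
2.262
2.317
2.334
2.340
2.346
2.378
2.483
2.683
2.835
2.835
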