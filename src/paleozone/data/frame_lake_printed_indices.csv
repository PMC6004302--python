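sample_id,depth,sdi_printed,dc_ratio_printed
FL1,1,2.41,0.7
FL2,2,2.14,0.7
FL3,3,2.47,0.55
FL4,4,2.49,0.69
FL5,5,2.65,0.66
FL6,6,2.36,0.63
FL7,7,2.09,0.2
FL8,8,2.38,0.21
FL9,9,2.37,0.26
FL10,10,2.2,0.3
FL11,11,2.47,0.33
FL12,12,2.27,0.32
FL13,13,2.06,0.28
FL14,14,2.41,0.45
FL15,15,2.45,0.4
FL16,16,2.6,0.54
FL17,17,2.61,0.62
FL18,18,2.59,0.68
FL19,19,2.45,0.57
FL20,20,2.38,0.66
FL21,21,2.48,0.8
FL22,22,2.36,0.85
FL23,23,2.26,0.89
FL24,24,2.39,0.9
FL25,25,2.19,0.92
FL26,26,2.37,0.86
FL27,27,2.42,0.77
FL28,28,2.57,0.75
FL29,29,2.35,0.8
FL30,30,2.27,0.82
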