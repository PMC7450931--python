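site,phase,n_meet,n_over
Medicine,before,33,84
Associated Medical Sciences,before,6,15
Pharmaceutical Sciences,before,3,16
Dentistry,before,7,17
Nursing,before,11,16
Veterinary Medicine,before,6,12
University Complex,before,11,45
Medicine,after,27,61
Associated Medical Sciences,after,10,8
Pharmaceutical Sciences,after,6,11
Dentistry,after,11,24
Nursing,after,10,11
Veterinary Medicine,after,2,11
University Complex,after,42,66
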