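((sp1_cA:0.250000,(sp2_cA:0.125000,sp3_cA:0.125000):0.125000):0.300000,((sp3_cB:0.125000,sp1_cB:0.125000):0.125000,sp2_cB:0.250000):0.300000,(sp1_mt:0.250000,(sp3_mt:0.125000,sp2_mt:0.125000):0.125000):0.300000,(sp1_er:0.250000,(sp3_er:0.125000,sp2_er:0.125000):0.125000):0.300000);
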