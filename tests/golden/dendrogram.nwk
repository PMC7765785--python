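((R-TOY-0003:0,R-TOY-0004:0):0.5,(R-TOY-0001:0,R-TOY-0002:0):0.5);
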