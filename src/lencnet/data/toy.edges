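# 6-node, 7-edge example network used in the golden worked-example tests.
1 2
2 3
2 4
3 4
3 6
4 5
4 6
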