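class,km2
linear,18.8
recreation_facility,12.8
settlement,8.4
industrial,7.1
farmland,0.4
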