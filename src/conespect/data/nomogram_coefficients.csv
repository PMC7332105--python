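family,k,coefficient
rgb,0,-93.262
rgb,1,617.458
rgb,2,-2815.735
rgb,3,7339.277
rgb,4,-10714.545
rgb,5,9048.982
rgb,6,-4410.667
rgb,7,1154.235
rgb,8,-125.738
uv,0,-48139.554
uv,1,309007.504
uv,2,-770875.542
uv,3,834365.023
uv,4,-57657.482
uv,5,-815689.388
uv,6,871189.984
uv,7,-389189.665
uv,8,66989.122
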