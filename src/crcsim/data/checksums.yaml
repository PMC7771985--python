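# sha256 of each fixture data file (version v1)
test_characteristics.yaml: a3c01f4ce07ccf0618b15538de018477865f44133bd4eecfa5cc865cbb21ddac
nh_params.yaml: 9392fa0f8d885e0f3654e1ebe014da104ee6b772732a3104cb308eb9f5c1516c
strategies.tsv: 7f6d8aad76eff1d5461194c9b8cb8d686891d32d37dbda955cadca4603f49847
life_table_synthetic_us1975.tsv: e4b75f139c82cc174c4f613a016eacdb02edc18e2cda146b8bb35689d6b97299
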