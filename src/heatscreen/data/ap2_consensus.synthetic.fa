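>ap2_consensus_synthetic AP2-domain-like consensus (synthetic stand-in, ~60 aa)
HYRGVRQRPWGKWVAEIRDPKKAARVWLGTFDTAEAAARAYDEAALRFKGNKAKLNFPER
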