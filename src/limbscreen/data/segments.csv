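artery,level
aorta,proximal
common_iliac,proximal
external_iliac,proximal
internal_iliac,proximal
common_femoral,proximal
profunda_femoris,proximal
superficial_femoral,proximal
popliteal,proximal
tibioperoneal_trunk,distal
anterior_tibial,distal
posterior_tibial,distal
peroneal,distal
dorsalis_pedis,distal
plantar,distal
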