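>master_consensus synthetic kinase catalytic-domain master sequence
MGSRKLGGKGSFGEVAVNGSGKILKVAAPERSVKTLEHLREAARINHPVLVKLITPNGSLGYCTEYMEGGDLFDYLRKSGLSPEHRNVFLSGNPILIHRDLAARNVLVKTTADFGLAGLDE
>variant_bulky_gk synthetic variant, M gatekeeper
MGSRKLGGKGAFGEVAVNGSGKILKVAAPERSVKTLEHLREAARINHPLLVKLITPNGSLGYCMEYLEGGDLFDYLRKSGLSPEHRNVFLSGNPILIHRDLAARNVLVKTTADFGLAGLDE
>variant_tk_like synthetic variant
MGSRKLGGKGSFGEVAVNGSGKILRVAAPERSVKTLEHLREAAKINHPVLVKLITPNGSLGYCTEYMEGGDLFDYLRKSGLSPEHRNVYLSGNPILIHRDLAARNVLVKTTADFGLAGLDE
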