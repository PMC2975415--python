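>hsH3.1 species=human family=H3 variant=H3.1
ARTKQTARKSTGGKAPRKQLATKAARKSAPATGGVKKPHRYRPGTVALREIRRYQKSTEL
LIRKLPFQRLVREIAQDFKTDLRFQSSAVMALQEACEAYLVGLFEDTNLCAIHAKRVTIM
PKDIQLARRIRGERA
>hsH4 species=human family=H4 variant=H4
SGRGKGGKGLGKGGAKRHRKVLRDNIQGITKPAIRRLARRGGVKRISGLIYEETRGVLKV
FLENVIRDAVTYTEHAKRKTVTAMDVVYALKRQGRTLYGFGG
>hsH2A.1 species=human family=H2A variant=H2A.1
SGRGKQGGKARAKAKTRSSRAGLQFPVGRVHRLLRKGNYAERVGAGAPVYLAAVLEYLTA
EILELAGNAARDNKKTRIIPRHLQLAIRNDEELNKLLGKVTIAQGGVLPNIQAVLLPKKT
ESHHKAKGK
>hsH2B.1 species=human family=H2B variant=H2B.1
PEPAKSAPAPKKGSKKAVTKAQKKDGKKRKRSRKESYSVKVYKVLKQVHPDTGISSKAMG
IMNSFVNDIFERIAGEASRLAHYNKRSTITSREIQTAVRLLLPGKLAKHAVSKGTKKVTK
YKSSK
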