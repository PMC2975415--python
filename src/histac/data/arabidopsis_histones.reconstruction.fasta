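>atH3.2 species=arabidopsis family=H3 variant=H3.2
ARTKQTARKSTGGKAPRKQLATKAARKSAPTTGGVKKPHRYRPGTVALREIRRYQKSTEL
LIRKLPFQRLVREIAQDFKTDLRFQSAAVKALQEACEAYLVGLFEDTNLCAIHAKRVTIM
PKDIQLARRIRGERA
>atH3.3 species=arabidopsis family=H3 variant=H3.3
ARTKQTARKSTGGKAPRKQLATKAARKSAPTTGGVKKPHRYRPGTVALREIRRYQKSTEL
LIRKLPFQRLVREIAQDFKTDLRFQSAAVKALQEASEAYLVGLFEDTNLCAIHAKRVTIM
PKDIQLARRIRGERA
>atH4 species=arabidopsis family=H4 variant=H4
SGRGKGGKGLGKGGAKRHRKVLRDNIQGITKPAIRRLARRGGVKRISGLIYEETRGVLKI
FLENVIRDAVTFTEHAKRKTVTAMDVVYALKRQGRTLYGFGG
>atH2B.6 species=arabidopsis family=H2B variant=H2B.6
AEKKTAEKKTAEPKKAEPAKAEPATPEPAKSAPAPKKGSKKAVTKAQKKDGKKRKRSRKE
SYSVKVYKVLKQVHPDTGISSKAAGIMNSFVNDIFERIAGEASRLAHYNKRSTISSREIQ
TAVRLLLPGKLAKHAVSKGTKKVTKYKSSK
>atH2B.7 species=arabidopsis family=H2B variant=H2B.7
AEKKVAEKKVAEPKKAEPSKAEPSVPEPAKSAPAPKKGSKKAVTKAQKKDGKKRKRSRKE
SYSVKVYKVLKQVHPDTGISSKASGIMNSFVNDIFERIAGEASRLAHYNKRSTIASREIQ
TAVRLLLPGKLAKHAVSKGTKKVTKYKSSK
>atH2B.10 species=arabidopsis family=H2B variant=H2B.10
AEKAGKEPAGKKPAGAEPAGPEPAKSAPAPKKGSKKAVTKAQKKDGKKRKRSRKESYSVK
VYKVLKQVHPDTGISSKAMGLMNSFVNDIFERIAGEASRLAHYNKRSTITTREIQTAVRL
LLPGKLAKHAVSKGTKKVTKYKSSK
>atH2A.1 species=arabidopsis family=H2A variant=H2A.1
SGRGKQGGKARAKAKTRSSRAGLQFPVGRVARLLRKGNYAERVGAGAPVYLAAVLEYLTA
EILELAGNAARDNKKTRIIPRHLQLAIRNDEELNKLLGKVTIAQGGVLPNIQAVLLPKKT
ESHHKAKGR
>atH2A.2 species=arabidopsis family=H2A variant=H2A.2
SGRGKQGGKARAKAKTRSSRAGLQFPVGRVHGLLRKGNYAERVGAGAPVYLAAVLEYLTA
EILELAGNAARDNKKTRIIPRHLQLAIRNDEELNKLLGKVTIAQGGVLPNIQAVLLPKKT
ESHHKARGR
>atH2A.3 species=arabidopsis family=H2A variant=H2A.3
SGRGKQGGKARAKAKTRSSRAGLQFPVGRVHRSLRKGNYAERVGAGAPVYLAAVLEYLTA
EILELAGNAARDNKKTRIIPRHLQLAIRNDEELNKLLGKVTIAQGGVLPNIQAVLLPKKT
ESHHKARGR
>atH2A.4 species=arabidopsis family=H2A variant=H2A.4
SGRGKQGGKARAKAKTRSSRAGLQFPVGRVHRLTRKGNYAERVGAGAPVYLAAVLEYLTA
EILELAGNAARDNKKTRIIPRHLQLAIRNDEELNKLLGKVTIAQGGVLPNIQAVLLPKKT
ESHHKAKGKSEPAGKEPKGSEPAKSEPAGSKAKAKAKAK
>atH2A.5 species=arabidopsis family=H2A variant=H2A.5
SGRGKQGGKARAKAKTRSSRAGLQFPVGRVHRLLVKGNYAERVGAGAPVYLAAVLEYLTA
EILELAGNAARDNKKTRIIPRHLQLAIRNDEELNKLLGKVTIAQGGVLPNIQAVLLPKKT
ESHHKAKGKAKAK
>atH2A.6 species=arabidopsis family=H2A variant=H2A.6
SGRGKQGGKARAKAKTRSSRAGLQFPVGRVHRLLRLGNYAERVGAGAPVYLAAVLEYLTA
EILELAGNAARDNKKTRIIPRHLQLAIRNDEELNKLLGKVTIAQGGVLPNIQAVLLPKKT
ESHHKAKGKTGPKSTGPKSTGPASTGPAKAKAKAKAKAK
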