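solvent_id,ei,notes
water,0.0,reference aqueous component
DMSO,11.7,EI dominated by photochemical oxidation potential
DMSO_adj,0.26,DMSO with photochemical contribution excluded (data-provenance adjustment)
DMF,2.0,
4FM,0.51,4-formylmorpholine; marginally above the 0.5 green threshold
DMAc,1.6,N-N-dimethylacetamide
dioxane,0.8,"1,4-dioxane"
transcutol,0.7,
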