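item,question,prevalence
somatic symptoms,1,0.054900
somatic symptoms,2,0.055551
somatic symptoms,3,0.021612
somatic symptoms,4,0.104639
fatigue,1,0.028229
fatigue,2,0.086979
fatigue,3,0.128571
fatigue,4,0.014318
concentration,1,0.109519
concentration,2,0.022198
concentration,3,0.108458
concentration,4,0.019662
sleep,1,0.265438
sleep,2,0.228699
sleep,3,0.074140
sleep,4,0.027105
irritability,1,0.149651
irritability,2,0.039839
irritability,3,0.107785
irritability,4,0.019005
worry about physical health,1,0.037338
worry about physical health,2,0.171928
worry about physical health,3,0.226391
worry about physical health,4,0.084403
depression,1,0.159012
depression,2,0.023677
depression,3,0.027354
depression,4,0.012284
depressive ideas,1,0.037236
depressive ideas,2,0.142137
depressive ideas,3,0.054308
depressive ideas,4,0.014392
depressive ideas,5,0.107385
worry,1,0.024504
worry,2,0.017612
worry,3,0.063111
worry,4,0.261125
anxiety,1,0.012659
anxiety,2,0.022211
anxiety,3,0.226802
anxiety,4,0.067408
phobias,1,0.027306
phobias,2,0.011491
phobias,3,0.029996
phobias,4,0.016692
panic,1,0.036585
panic,2,0.024612
panic,3,0.012424
panic,4,0.035443
compulsions,1,0.014105
compulsions,2,0.013003
compulsions,3,0.054438
compulsions,4,0.326133
obsessions,1,0.049223
obsessions,2,0.244411
obsessions,3,0.011976
obsessions,4,0.022873
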