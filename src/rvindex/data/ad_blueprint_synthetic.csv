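region_id,modality,d
bankssts,cortical_thickness,-0.177
caudalanteriorcingulate,cortical_thickness,-0.112
caudalmiddlefrontal,cortical_thickness,-0.717
cuneus,cortical_thickness,-0.431
entorhinal,cortical_thickness,-1.1
fusiform,cortical_thickness,-0.85
inferiorparietal,cortical_thickness,-0.6
inferiortemporal,cortical_thickness,-0.9
isthmuscingulate,cortical_thickness,-0.649
lateraloccipital,cortical_thickness,-0.466
lateralorbitofrontal,cortical_thickness,-0.302
lingual,cortical_thickness,-0.103
medialorbitofrontal,cortical_thickness,-0.68
middletemporal,cortical_thickness,-0.95
parahippocampal,cortical_thickness,-0.75
paracentral,cortical_thickness,-0.604
parsopercularis,cortical_thickness,-0.721
parsorbitalis,cortical_thickness,-0.18
parstriangularis,cortical_thickness,-0.506
pericalcarine,cortical_thickness,-0.458
postcentral,cortical_thickness,-0.213
posteriorcingulate,cortical_thickness,-0.55
precentral,cortical_thickness,-0.806
precuneus,cortical_thickness,-0.6
rostralanteriorcingulate,cortical_thickness,-0.385
rostralmiddlefrontal,cortical_thickness,-0.98
superiorfrontal,cortical_thickness,-0.346
superiorparietal,cortical_thickness,-0.918
superiortemporal,cortical_thickness,-0.7
supramarginal,cortical_thickness,-0.706
temporalpole,cortical_thickness,-0.8
transversetemporal,cortical_thickness,-0.199
insula,cortical_thickness,-0.661
thalamus,subcortical_volume,-0.35
caudate,subcortical_volume,-0.2
putamen,subcortical_volume,-0.3
pallidum,subcortical_volume,-0.15
hippocampus,subcortical_volume,-1.2
amygdala,subcortical_volume,-1.0
accumbens,subcortical_volume,-0.5
acr,white_matter,-0.473
alic,white_matter,-0.408
bcc,white_matter,-0.226
cgc,white_matter,-0.45
cgh,white_matter,-0.7
cr,white_matter,-0.192
cst,white_matter,-0.214
ec,white_matter,-0.335
fx,white_matter,-0.8
fxst,white_matter,-0.6
gcc,white_matter,-0.661
ic,white_matter,-0.244
ifo,white_matter,-0.477
pcr,white_matter,-0.395
plic,white_matter,-0.087
ptr,white_matter,-0.164
rlic,white_matter,-0.022
scc,white_matter,-0.356
scr,white_matter,-0.143
sfo,white_matter,-0.428
slf,white_matter,-0.393
ss,white_matter,-0.335
unc,white_matter,-0.55
cc_total,white_matter,-0.5
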