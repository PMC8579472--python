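# fegrad reference charged side-chain hydration free-energy budgets (kJ/mol)
# columns: system, force_field, expt, raw_plus_cav, raw_se, dG_ABD, dG_C1, dG_std, dG_hyd
system,force_field,expt,raw_plus_cav,raw_se,dG_ABD,dG_C1,dG_std,dG_hyd
ARG,54A8,-276.5,-137.9,0.4,-58.6,-67.8,7.9,-256.5
ARG,SIRAH1,,-149.0,0.6,-57.5,-7.2,7.9,-205.8
ARG,SIRAH2,,-149.9,0.6,-57.5,-7.2,7.9,-206.6
ARG,HFE-fitted,,-223.7,0.5,-54.8,-7.2,7.9,-277.8
LYS,54A8,-289.5,-180.1,0.6,-58.8,-67.8,7.9,-298.8
LYS,SIRAH1,,-134.5,0.6,-54.7,-7.4,7.9,-188.7
LYS,SIRAH2,,-130.9,0.5,-54.7,-7.4,7.9,-185.2
LYS,HFE-fitted,,-178.6,0.6,-57.5,-7.4,7.9,-235.8
GLU,54A8,-315.4,-349.9,0.5,-58.9,67.8,7.9,-332.9
GLU,SIRAH1,,-156.4,0.4,-58.8,7.5,7.9,-199.3
GLU,SIRAH2,,-153.6,0.5,-58.8,7.5,7.9,-196.5
GLU,HFE-fitted,,-252.8,0.6,-58.3,7.5,7.9,-295.6
ASP,54A8,-321.2,-349.4,0.5,-58.9,67.8,7.9,-332.5
ASP,SIRAH1,,-156.4,0.4,-58.8,7.5,7.9,-199.2
ASP,SIRAH2,,-153.6,0.5,-58.8,7.5,7.9,-196.4
ASP,HFE-fitted,,-252.8,0.6,-58.3,7.5,7.9,-295.6
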