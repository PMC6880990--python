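cui,string
C0002395,alzheimer's disease
C0002395,Alzheimers Disease
C0002395,senile dementia
C0011570,depression
C0011570,depressive disorder
C0154409,major depressive disorder single episode
C0154417,major depressive disorder recurrent episode
C0004352,autism
C0004352,autistic disorder
C0029132,optic neuritis
C0017612,glaucoma
C0023508,leukocytosis
C0023508,elevated white blood cell count
C0037303,skull fracture
C0035522,rib fracture
C0014544,epilepsy
C0497327,dementia
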