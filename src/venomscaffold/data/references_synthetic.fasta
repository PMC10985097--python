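>ref_ShKT_synthetic family=ShKT synthetic exemplar realizing C-C-C-CX3CX2C
GYCPAYGCMKESVFYHCYHMVNLARNICQDDCVQC
>ref_beta-defensin_synthetic family=beta-defensin synthetic exemplar realizing CXC-C-C-CC
WCQCQEKGQEWKVKTCIEDPNCHWTRIPKTGQCCD
>ref_Kunitz-type_synthetic family=Kunitz-type synthetic exemplar realizing C-C-C-C-CX3C
SCAWFSYIWICTHKVENGYCSWEYRGQLCDEWRLEACLNECTGFR
>ref_EGF-like_synthetic family=EGF-like synthetic exemplar realizing C-C-C-CXC-C
CTRTTMGCLHGKTWMKPWCMREHVYCACPLPISVSCKDYA
>ref_ICK_synthetic family=ICK synthetic exemplar realizing C-C-CC-C-C-C-C
CEFKERWQCVWGDQRKYVCCTKFVLFCIDLLVFAEEWSCIAFKIRQCHKISIWVACYL
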