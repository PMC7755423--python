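property,category,description
hydrophobicity1,basic,"Kyte-Doolittle scale rescaled to [-1, 1]"
charge,basic,Henderson-Hasselbalch fractional side-chain charge at pH 7.0
hydrophobicity2,basic,"Eisenberg consensus scale rescaled to [-1, 1]"
side_chain_flexibility,basic,rotatable side-chain dihedral count
side_chain_bulk,basic,Zimmerman bulkiness
kidera_1,kidera,orthogonal standardized factor (PCA of classic scales; reconstruction)
kidera_2,kidera,orthogonal standardized factor (PCA of classic scales; reconstruction)
kidera_3,kidera,orthogonal standardized factor (PCA of classic scales; reconstruction)
kidera_4,kidera,orthogonal standardized factor (PCA of classic scales; reconstruction)
kidera_5,kidera,orthogonal standardized factor (PCA of classic scales; reconstruction)
kidera_6,kidera,orthogonal standardized factor (PCA of classic scales; reconstruction)
kidera_7,kidera,orthogonal standardized factor (PCA of classic scales; reconstruction)
kidera_8,kidera,orthogonal standardized factor (PCA of classic scales; reconstruction)
kidera_9,kidera,orthogonal standardized factor (PCA of classic scales; reconstruction)
kidera_10,kidera,orthogonal standardized factor (PCA of classic scales; reconstruction)
hotspot_1,hotspot,synthetic standardized placeholder descriptor
hotspot_2,hotspot,synthetic standardized placeholder descriptor
hotspot_3,hotspot,synthetic standardized placeholder descriptor
hotspot_4,hotspot,synthetic standardized placeholder descriptor
hotspot_5,hotspot,synthetic standardized placeholder descriptor
hotspot_6,hotspot,alpha-helix propensity (standardized)
hotspot_7,hotspot,synthetic standardized placeholder descriptor
hotspot_8,hotspot,synthetic standardized placeholder descriptor
hotspot_9,hotspot,synthetic standardized placeholder descriptor
hotspot_10,hotspot,synthetic standardized placeholder descriptor
hotspot_11,hotspot,synthetic standardized placeholder descriptor
hotspot_12,hotspot,synthetic standardized placeholder descriptor
hotspot_13,hotspot,synthetic standardized placeholder descriptor
hotspot_14,hotspot,synthetic standardized placeholder descriptor
hotspot_15,hotspot,synthetic standardized placeholder descriptor
hotspot_16,hotspot,synthetic standardized placeholder descriptor
hotspot_17,hotspot,synthetic standardized placeholder descriptor
hotspot_18,hotspot,synthetic standardized placeholder descriptor
hotspot_19,hotspot,synthetic standardized placeholder descriptor
hotspot_20,hotspot,synthetic standardized placeholder descriptor
hotspot_21,hotspot,synthetic standardized placeholder descriptor
hotspot_22,hotspot,synthetic standardized placeholder descriptor
hotspot_23,hotspot,synthetic standardized placeholder descriptor
hotspot_24,hotspot,beta-sheet propensity (standardized)
hotspot_25,hotspot,reverse-turn propensity (standardized)
hotspot_26,hotspot,synthetic standardized placeholder descriptor
hotspot_27,hotspot,synthetic standardized placeholder descriptor
hotspot_28,hotspot,synthetic standardized placeholder descriptor
hotspot_29,hotspot,synthetic standardized placeholder descriptor
hotspot_30,hotspot,synthetic standardized placeholder descriptor
hotspot_31,hotspot,synthetic standardized placeholder descriptor
hotspot_32,hotspot,synthetic standardized placeholder descriptor
hotspot_33,hotspot,synthetic standardized placeholder descriptor
hotspot_34,hotspot,synthetic standardized placeholder descriptor
hotspot_35,hotspot,synthetic standardized placeholder descriptor
hotspot_36,hotspot,synthetic standardized placeholder descriptor
hotspot_37,hotspot,synthetic standardized placeholder descriptor
hotspot_38,hotspot,synthetic standardized placeholder descriptor
hotspot_39,hotspot,synthetic standardized placeholder descriptor
hotspot_40,hotspot,synthetic standardized placeholder descriptor
hotspot_41,hotspot,side-chain flexibility (standardized)
hotspot_42,hotspot,synthetic standardized placeholder descriptor
hotspot_43,hotspot,synthetic standardized placeholder descriptor
hotspot_44,hotspot,synthetic standardized placeholder descriptor
hotspot_45,hotspot,synthetic standardized placeholder descriptor
hotspot_46,hotspot,synthetic standardized placeholder descriptor
hotspot_47,hotspot,synthetic standardized placeholder descriptor
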