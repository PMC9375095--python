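>circle_part_1 end5=phosphate role=circle_part
TTTATCTATATCTGCCACGCTACTTACGTCTCTCGTCTGATGCTCCACCTCATATATAAATTGTGTCCACTCGTCTCACTGCTCAACTACCTACCTCAGGAGAAACCTTTACTT
>circle_part_2 end5=phosphate role=circle_part
CGAGGTGCTTTTAGCACCTCGAAGTAAAGCTATCCACTGTCACCAACTACTAGATAAACGTCACACTTTTCGTGTGACG
>arm_A end5=aldehyde role=arm
AAAAAAAAACTCCTGAGGTAGGTAGTTGAGCAGCATCCGCACTTATAGCTGCAGTGAGACGAGTGGACAC
>arm_B end5=aldehyde role=arm
AAAAAAAAATGAGGTGGAGCATCAGACGGTAATTAACCCGCCCCGTACGAGAGACGTAAGTAGCGTGGCA
>tag_A end5=phosphate role=tag
CTGCAGCTATAAGTGCGGATG
>tag_B end5=phosphate role=tag
CGTACGGGGCGGGTTAATTAC
>detection_A end5=fluorophore role=detection label=TexasRed
CTGCAGCTATAAGTGCGGATGUUU
>detection_B end5=fluorophore role=detection label=Atto647N
CGTACGGGGCGGGTTAATTACUUU
>padlock_A end5=phosphate role=padlock
AGTGCGGATGCTGCTCAACTACCTACACCTCGAAGTAAAGCTATCCACTGTCACCAACTACTAGATAAACGTCACTCCACTCGTCTCACTGCAGCTATA
>padlock_B end5=phosphate role=padlock
GGTTAATTACCGTCTGATGCTCCACACCTCGAAGTAAAGCTATCCACTGTCACCAACTACTAGATAAACGTCACCTACTTACGTCTCTCGTACGGGGCG
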