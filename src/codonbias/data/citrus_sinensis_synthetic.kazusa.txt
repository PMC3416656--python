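# SYNTHETIC stand-in for the Citrus sinensis codon-usage table in
# Kazusa Codon Usage Database standard format. Counts reconstructed
# from published CS RSCU values and CTV amino-acid frequencies; not
# the real database entry.
fields: [triplet] [frequency: per thousand] ([number])

UUU 27.3( 16958)  UUC 24.7( 15343)  UUA 12.3(  7647)  UUG 22.4( 13904)
UCU 23.0( 14289)  UCC 12.8(  7973)  UCA 22.2( 13772)  UCG 11.8(  7352)
UAU 19.7( 12228)  UAC 17.8( 11063)  UAA  0.6(   360)  UAG  0.6(   360)
UGU 11.8(  7309)  UGC 12.2(  7608)  UGA  0.6(   360)  UGG 10.6(  6600)
CUU 25.3( 15692)  CUC 14.5(  9038)  CUA  8.5(  5264)  CUG 12.8(  7945)
CCU 12.2(  7572)  CCC  8.1(  5029)  CCA 11.6(  7225)  CCG  5.3(  3295)
CAU 10.8(  6703)  CAC  9.2(  5710)  CAA  9.2(  5700)  CAG  8.1(  5055)
CGU  8.3(  5181)  CGC  6.9(  4266)  CGA  7.1(  4419)  CGG  6.6(  4114)
AUU 19.5( 12099)  AUC 13.2(  8213)  AUA 10.0(  6182)  AUG 22.2( 13800)
ACU 19.3( 11979)  ACC 11.0(  6857)  ACA 15.7(  9748)  ACG  7.0(  4378)
AAU 21.4( 13310)  AAC 18.6( 11568)  AAA 22.1( 13720)  AAG 29.3( 18187)
AGU 14.5(  9008)  AGC 15.5(  9630)  AGA 22.3( 13866)  AGG 22.3( 13866)
GUU 36.6( 22757)  GUC 15.2(  9470)  GUA 10.9(  6785)  GUG 28.2( 17527)
GCU 24.1( 14978)  GCC 13.1(  8152)  GCA 16.9( 10522)  GCG  6.9(  4266)
GAU 39.2( 24352)  GAC 21.6( 13403)  GAA 23.7( 14700)  GAG 26.2( 16247)
GGU 16.5( 10252)  GGC 14.5(  8982)  GGA 15.6(  9707)  GGG 11.8(  7349)
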