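>gstn_consensus synthetic
MSNCNAMEKNPQGKNKDMKIMWIQSENPDHPHFLKGGIFRWHAPKRWTVLSWLFNNDSEQHWDHHENFRFRDWFQCLNTVCQFAADKETLLLDNL
>gstn_variant_1 synthetic
ISNKNAMIKCENCRNKDMKILWIQTEGPDHPHFLQGGIFKWHAPKKFTMLSWLMNNQSEQHWDYHQHFRFRDWFQCFNTMCQFAADKETLLIDNL
>gstn_variant_2 synthetic
MSNTNAMEKNPQGQEKEMKIVWIQAENPDHPHFLKNYVCRWHAPKHWTVLGWLINDDTEQHYDHHEQIRFQDWSQCMNSICQFAADQATELLQHI
>gstn_variant_3 synthetic
ISNCKAMEQEHEGYNKEMNIMMIQSYHMDNPHLLKGGVCRYYAPKRWDVLFWLFNNDSEQHWDNKENFRFFNWFKLLNTVCHFATNKTSLYLDNY
>gstn_variant_4 synthetic
VSNCKSCMNNPRGKHFDMKIMWVQSEVPDHHHNLKWNIFHWFAPSQFSRLSWLSNNDSEEHWMHYPNFRLRDYFECLNTVCQFSSDKNSLIMENR
>gstn_variant_5 synthetic
ASECNAIEKNPNFHEKDIRKTKVLSEIPDHPYFIKGGIFHWHAPKHWTVLTWLFNEQAEKFWQPRQQFRYHDYYQCLKTVQAFAAEQNTLVMQNL
>gstn_variant_6 synthetic
LSNCQATEKNANGKNYPMMMMYTNADEPQHTHQLKGGLFQDHAPKRETRHVFWLLFDSDRHIKKHKNYRFRHFFQCLNTVGQSATDRKTYLWHNH
>gstn_variant_7 synthetic
MAQCRSMEHNLLGKRNLMVIMFHDSNWQQHPTFLHFGLLRIHAPERFPVLSWFFNNDNENKWFHHEQADWQDWADILITRIHFNAQRGALVYCNM
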