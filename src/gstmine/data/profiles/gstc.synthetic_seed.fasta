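>gstc_consensus synthetic
APLVVCLDGQINQLAVAKDHLTTESTMKWDCGFITPDPRIPMKWQHVDWQGFYHMLYSTSHTMERPTHNEGMTNLEIYTSFDNQWYMWNGSFIILRFMRCYIYPE
>gstc_variant_1 synthetic
SRLVIRLDGQINQLAIMKDHLTTESAMKWNCGFITPQPRIPIKWKHSDWQRFYNMLYSTSHTMEQPTHNQGMTKLKIITIYQEQWYMWNGAYIILQFMRCYIGPE
>gstc_variant_2 synthetic
FLLVACMDIRIFQLAVAKEHLTSESTMIFDEGWITPDPRIPMQWQHVDWQAFHHMLKSTSQTLERPTHCEGMSNLEIASSFNNQWWIWKGSFLILRFMQCYLCPG
>gstc_variant_3 synthetic
APFVLCLDGQINQLTIAKNHMTTQTTLKWWRGFIAPWMPLPKNFIHVAWQKMYHMIYSTSHTIERPTHNEGMTRFNIYSSMDYQWFMYNGTFIILRQMRCYIYND
>gstc_variant_4 synthetic
APLVLCEDGQINFLSMAKDHITTASTADWSSGFLTLDVRIPIQWNQVKGQGFQHMLNSTSHTFERYTYKEGMTNLEMYTVYDDQEYFFRGSHIRIHFPRRYVYLE
>gstc_variant_5 synthetic
FPLVMCLDRVFNQMTVAKDYITTEAGMQPDCGFVTYDPRFKLQWQWFDTDGFYHMMNSAFHMMQRASHNEDFFELEVYTSYDNQWYYFNGTYIFVKWMVCYQYVE
>gstc_variant_6 synthetic
APIMPCMDRQINQLAVAKEHMTTESTVKFSGGLISTGPRMPFKFDHLTWYGFIHFIYTTAHTMERFTRNEGISQLKYRAEFDNEYHYFIGSYLFLQFYTCQYQSE
>gstc_variant_7 synthetic
APIVVTLNGQKAQLSVAIENMTFDAAMPWNMYFIHTQFRHPMHLERKEWKGFQGILMASSHSMQRLAHNEGMCKFEIYQAIKNHWYMGNWAMILLRHMHFFIYPY
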