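>mapeg_consensus synthetic
QIPQYRAYWRAGIHGPQPHIDCQQLFAREPEYMWQAFIRVARCDLFKRPNHYDDKSNMIRVERVRRAHLNDGENISDKPGGIVHVEQRCHCHSMAWFNTNHLCYRENKWLQFDGKWIQFKWGLYAHHHSPHGTCEIDNGP
>mapeg_variant_1 synthetic
QIPQYRSYWRAGIHGSQPHIDCEQLFLKNHEHMWVSFIRVIRCDLYKRGNHYDDKSNMQRVERVRRAHLNDGENISQKPGQIVHIEQHCHRYAMTWFNANHLCYFEVKWLQFNGPYIQFKWGLYAKYHAPYGTNEINNWP
>mapeg_variant_2 synthetic
QSPQYRAYWRAMIHNDYTHIDYQQLYAHEPEYMWQPWMRIARCELMKRPNYFDQKSKNVQVERVRRAHLNDGENISDKLGRIVYVEQRCPSHSMAFFNTNYLCYREKQFLMFDGKWLMFKWGLFSHHHSPRLSCELDEGP
>mapeg_variant_3 synthetic
IIKNHRSYWRAMTHAPQPQHHLENQFAKTVEYDYPSFIVMTRCDVFHRPNHYDDKCNFIVVERVRRAHLNDGENISKKPGTLVHVEQQYHCHSMAWFTTNNLCYGQEKWRDFRGKWIQFKWELYSHHHSIHGTCEDDQRP
>mapeg_variant_4 synthetic
QIPQARAPFRYTIHGPKPKHDCQDLFAREPEWMYQAFRRVMRADTICHINHYEDHTNMLRVERVRRAHLNDGENISDKKGGIVHMENDSMCHSIAHFNADHLHYSGNKYLRVRSQFGQFRHGLHAHYYSPYSSKEINNIN
>mapeg_variant_5 synthetic
NMLRHHLYWKMAIGYPQPHIQCQQLFVKNPEYMYKAFMRVAKKDHKNQPNYYHDKAKMAHVERVRRAHLNDGENISNKPGIIVELEDKCHWHSLTFLNINQLCYRNDKFYQYEVKWIKFIWGFWGHNHSPHKADKIEQGP
>mapeg_variant_6 synthetic
QRNRYRDYNKAGFNGDYPHMDKKSLFSREPEMIWESVLVVSTCDVFQRPNRRYDHTNMQHVERVRRAHLNDGENISEQPFGIVHLQEQQHCHTLPWCEQPHACHHEERFCKFRSFTINFKWGLWAEHHSTHQTHQHDNSM
>mapeg_variant_7 synthetic
QIGQHKSYFRRCIHDKKEYLDQRNWFAHPPEYMTASSIQASSCNLFYRTNHSDDHSKRMHVERVRRAHLNDGENISDNIGFLIQMQQHCYDHMMSFYNSNKMCFQKNKYVQTHVIFHKTNFMIYIHAHSPHASCECDNEP
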