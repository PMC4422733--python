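>thx_consensus synthetic
WFHKRTYFTEGVFIKACTQQELCTRIAHLIMQHRQDQYAMQKIQHDMQRKFPLTGYAVEYPRHDHWLVLIVNDIAYLKPYKNRGG
>thx_variant_1 synthetic
WFYKQTYFTHNVFIHYCTKHDLCTRIAQLIVQHKQDQYLKQNIQHDVQRKFPLTGYAVIWPRHDHYLVLILNHIAYLHPYKNRGG
>thx_variant_2 synthetic
WIHKRAYFTEPMFVKACAETFLCARLAHLYMQHRQDLYAMQKIHHNMQRQFPLTAYAVEYYRHNLWLVVIVNAIAYAKDQKKRGG
>thx_variant_3 synthetic
FWRNYTYFAGHVYIKACAMQNLCTRLAHLTMQYRQQQYAMQKIQHDQQQKAPLTGYAVEHPRHEKALMLLVNNIAYNLPYKERNG
>thx_variant_4 synthetic
WFHQRQYETQGDWIKACFIPEICFRIAHCVFNHYNDQYALQKAQHDMCWKFPMTGHAVEYPKHDKWLKLIINDYAYLELYSFEGS
>thx_variant_5 synthetic
QFQKKTTMKNCVFYKTCAEEELNTRIAHSIIQMRSDFYAMKKIQYDNQRKQPLFGYPLNDPRYNHWLMIHVDDLAYLKPDKDRHC
>thx_variant_6 synthetic
LFHKRTYEINDVFVKTCVQYNDCRKIAHDILHRRPDEYAMWCVQKDLIRPLPLAPYMVLHPRRDHWLVVFINNMAHFKPYSDRNG
>thx_variant_7 synthetic
WIYKKTHFAPHVMIEANTCQQWCTPIAEKYMQRKYDEYEMKHIQHDMQHHSPWTFMNVSYPHHQHPMVFLMNDDTYVKNFRNYGH
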