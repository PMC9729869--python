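>SYNREF_I_archaeal_a synthetic I reference (generated, seed=101; not a real homolog)
WPSCVIKMTINSELIHESWPITNKQRIERSMIFNLQQKREQRASIWFPAPPALYGCRHLEGQPYTHTVMH
VAEECYPWSFSGHIWSGEGMNQECWWPSCILNELGLSIRFVNKFLHAAQSYCNKLTIWYWNNAGMPPQQC
KVEIGFGNFPASIWGWIGDDTMDMLKRISMCKCYNSSCLWICSCARSLGTCCLFESNVEGTRFLAKPIWF
KIHHYISGCIVVKFYVANVGYTGFFCSYELQGCFMVCFMMKHQWQGNCKMQKTKIRGHTSTIDDSPDKMV
LCQGLYPSLCSMEHAPTCQCPCKAQGTQFHRSLPIMQGHVTMKRVCCVFA
>SYNREF_I_archaeal_b synthetic I reference (generated, seed=102; not a real homolog)
PHWHQMRYYCVWVHQSKVGECHYSVKVVGTRTEKENQIVRRQYAPIEDDCTDWSLNTWSVIQKIYWHWPV
CQFTHMEVQLRHINSIHKVRGGTWKAEKQLGFFGARLNLSRKRIMIASISYIKLEHQTGALLRKHRKHEF
TFHLHHCIGGSQTENWGSSKGALYLWGTIEEWISALVTWYHTLLFHLWEFFIGEHQKRGNTLPLSKITIQ
FCNPTWECSIASADDQPDTQCSISQKLNHLIFIMEFWLMVIIEAHWKKLAISQKYHQTVAWARMVEVKNR
FQERETTKPAFMANTVCHIIQKQNWGVAEVVM
>SYNREF_II_plant_a synthetic II reference (generated, seed=203; not a real homolog)
TIALKAKPFGFFWPYLYQSITFMESSLHCAQGTDDCVLCDNCKHCGEEEQILLMTVECHRCTVCNGPPCI
YCQQMGSMAGTAKSEHEIKWFAWKFGQELMVEELKMWHRFLRFRWAERPNQFELKIHFMGETVKAFLYVM
QYTFFCQRCYARSPDDLRDLHHNFWCPLGNSWYMGYSPIHSAQHPVMLTVCRTRCSFLNLVQHAVQTLLS
CTKYFWLNPMELGGHIRNKPCWHVEGLTYHIFCGCTLYHEAIHFACILYWSRNYKKRCSIKEQNHWAKAK
SMHSRRHMGPTEVEFEEFLGRGTYFNPGGYAMREYFCESRAYTHKAHTEFWCVPNCPLNVVKNSKNHKAR
AELCCGRRERQRFTMTHRTKR
>SYNREF_II_bacterial_a synthetic II reference (generated, seed=204; not a real homolog)
YIGRTNFYHNRESESVPGIKMKIHMSQINLGQVCGYWSSQPVESSNHSMASVGSVQQPRAMIEGWYSCSY
YWPPMRFQPVLPSMIHWQIHQWHTPAIFITSMIRSSSCPLQDDVAIWDAEVAHMFMYPSHWPMNWKVCPH
NQANHPSPTYLQHPVESIEPVVVPFFCQAWVPQIWEFKKRAIPLAMQHSGVKNKCCYWWKKCWMYNQTIP
MDDVYDWSPGRAFMYGYIYQKHYYKCKEYCQQENEKFFTRYVELSKVYPVIVMWKRSRKRNLMMREQKGL
WIQFRTFWVFLKAQPRTLRNKLVMH
>SYNREF_III_fungal_a synthetic III reference (generated, seed=305; not a real homolog)
YQMVHHHTYMIHCSTKLKLAGGYWCPTLKSTGYWEIHNTVMFLVYFKGFYEAAIGRDDRMMGDNMHSFLM
SPACWGWLLYGHTHGPCHCQVELKCHSTNKTQWMGENKRHPWHQFLANRTPEVGIEKIRWGYATVCIHIS
SQMRMQSHITHLITGENCTYIKWPRYCGENGPRESQERIEKWEQEMRPKQNIMQWMLKAKIKRSGTQHFH
LIAHVFHLGHMNATDDKTDVNRSELPKSWISPLNWHVLYTTVERMCPGSVFLAQTMKATCHMEVFPSKHH
MIMYHKECAMPTQTMQQVCQEGENQPWVEQVQLVMRTLFQKMERMYKYSFFWRRLTGLAHLCNGYLSVSV
RFLIREQPKIMYPWRHWPRSIVMCLFP
>SYNREF_III_fungal_b synthetic III reference (generated, seed=306; not a real homolog)
ILIRQWCCPEYVLMRIRCWLCWMNLQLKSYWNVATLVMIWCQVICGLLYQHQMHPVPFCWKKGKTKAFIV
YKYCNIEMNHPMVHIQFFLELAFPYWQPVLREWPTYYPNSRQESWCALQYDDFFLLDMPWYEWTNWCATH
VPLSGLWESTSIRCVKWTYINVSTSQVRGKVLPCGVCFMQFNWETIGCARYFWICWPGLKEHYEYKVTME
HPPWCAHFVKYKCLAMHTAEVTAVFKCSATRHTALICLWLSGMTHHSECIYSEKRVTLQWVCCRHYMDDF
LDMACYAGYTLINNNMGQIHTKCFYPWWKQTWYPHIYKYVLAYSGSQTYAVYMHFVPCNY
>SYNREF_III_animal_a synthetic III reference (generated, seed=307; not a real homolog)
MMVTRLAQIYPFISMQCGNKWKHQHVEHNSPFCALATLGSIAGGFGTMMIRFMNEELEYWIWFCNHKMAK
NFGLHPEERQLCFVHMMYPSIGQCKKIQMMGGPRYQKVQEKGGQNMSYPKTMVENIYMLSWNNYHYEPTL
YKLMAIEVTITMNKKAHIFYPCIYLCWVGARPTDDQWSFDTWTVQMVKIQSSPQMVLSIMAYSTEYRVNM
PWWIASSMHYSYEWWLVISTFFNAACVGKWKWGVFIPYWLGVERHEKINWSFERQCLYPNRGCGHQKRLG
KYLMRPKICTALMKFDDTCD
>SYNREF_III_animal_b synthetic III reference (generated, seed=308; not a real homolog)
QPPVLHRMRYRNHHWEEFCSKTAQRWLSWCLQNQVVLIISKNVVGCTWLPEYGGRYLDDYYRVDFPNTFN
QMFMLWYERQAQHHLYNLKSPVESGMHCNLQCQNYPWVKAVRHSVSQEMHGIVIYRAASNEWHFHNLPIV
FLFQVWNGEPFNVYKHENSYARALMDDTHDGHETWTIIFAMHYHYAAMYPIRAGNLPSMHLYKEEFYLIR
QGSNWPTNIKGLNVYRFKSHMPSCSNYQETNTPNKQNRPNTFAEWPPFERKRCLPIGYQTHTKFNESLIS
CCPVTNVHAGWLQKGPAQGTFPPRISVVGFLEMFNEYFKITLWTFWLNKGPVTKF
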