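>sp1_cA
FALEKKTNYSGIGPFQHGKVEIIADQVTNFTRTSNDTKLRAYKSKGVAIAVLLFYFPGLAPGGPSSDVSEPQRLGYTCEPGQIHGALTVPPCLIGAKTPSSRYHMYSPNRPESSRCYGMVNVRFMLTADCQWGCIVLEPATVAACRQLFSINCLAPVALNLSVQLRKVFTRHVAGCCSTRVLCGLAKTTTMSFPNLLEEVD
>sp1_cB
SAVQQKTNYSGIGPFQHGKVEIIADQVTNFTRTSHDIQLRGNKTKGEAIAVPLFYLPGLASGGPSRDVSEPQRLGCTCEPGEIHGALPVPPCQIGAKTPSRYHMYSTNGPESSRCYGMVNERFILTADCQWGCIVLKPATLAVCRRLFSLNLLAPCALKQSVRPREKVTRHVVRCCSTRVLCGFSKTSTLSFPSLLEEVD
>sp1_er
SALQRQTNYSGIGPFKNGRVEIIADQVTNFIRTSNDTQLRRNKTKAEAIAVSLFYFPGLASGGPSRDVSEPQRLGCTCEPGEIHVALPVTPWQIGAKTPSRYHMYSTNGPESSRCYGMLNERFILTADCQWGFIVLKPATVAVWRRLFSLNRLAPFALKLSVRLREMVTRHVVGCCSTRVLCGLSKTSTLSFPSLLKDEL
>sp1_mt
SALQRKTNNSGIAPMEGKTPKVLEAEVTSFTRTSNDTQLRRNKTKGEAIAVPLFYLPGLASGGPSRDVSEPQRLGCTCEPGEIHGALPVPPWQIGAKTPSRYHMYSTNGPESSRCYGMLNERFILTADCQWGCIVLKPATVAVCRRLFSLNRLAPFALKLTVRLREMVTRHVVGCYSTRVLCGLSKTSTLSFPSLLGSSA
>sp2_cA
FELQQKTNYSGIGPFQHGKVEIIADQVTNFTRTSNDTKLRGYTSKGEAIAVPLFYLPGLASGGPSRDVSEPQRLEDSCEPGEIQGAPTVPPCLIGAKTPSSRYHMYSSNRPVSSRCYGMVYERFILTADCQWGCIVLKPAKLAACQQLFSMNCLAPFALKLSVRLRKMVTRHVAGCYSTRVLCGLAKTSTLSFPSLLEEVD
>sp2_cB
SAVQQKTNYSGIGPFQHGKVEIIADQVTNFTRTSNDIQLRGNKTKGEAIAVPLFYLPGLASGGPSRDVSEPQRLGCTCEPGEIHGALPVPPCQIGAKTPSRYHMYSTNGPESSRCYGMVNERFILTADCQWGCIVLKPATLAVCRRLFSLNRLAPCALKLSVRLREMVTRHVVRCCSTRVLCGLSKTSTLSFPSLLEEVD
>sp2_er
SALQRKTNYSGIGPFKNGRVEIIADQVTNFIRTSNDTQFRRNKTKAEAIAVPLFYLPGLASGGPSRDVSKPQRLGCTCEPGEIHVALPVTPWQIGAKTPSRYHMYSTNGPESSRCYGMLNEPFILTADCQWGFIVLKPATVAVCRRLFSLNRLAPFALKLSVRLREMVTRHVVGCCTTRVLCGLSRTSTLSFPSLLKDEL
>sp2_mt
SALQRKTNNSGIAPMEGKTPKVLEAEVTSFTRTSKDTQLRRNKTKGEAIAVPLFYLPGLASGGPSRDVSEPQRLGCTCEPGEIHGALPVPPCQIGAKTPSRYHMYSTNGPESSRCYGMLNERFILTADCQWGCIVLKPATVAVCRRLFSLNRLAPFALKLSVGLREMVTRHVVGCCSTRVLCGLSKTSTLSFPSLLGSSA
>sp3_cA
FALQQKTNYSGIGPFQHGKVEIIADQVTNFTRTSNDTKLRGNKSKGEAIAVPLFYLLGLASGGPSRDVSEPRRLGDSCEPGHILGAVTVPPCLIGAKTPSSRYHMYYSNRPESSWCYGMVYERFILTADCQWGCIVLKPATLAACRQLFSMNCLAPFAFKLSVRMRKMVTRHVAGCYSRRVLCGLAKTSTLSFPRLLEEVD
>sp3_cB
SAVQQKTNYSGIGPFQHGKVEIIADQVTNFTRTSNDIQLRGNKTKGEAIAVPLFYLPGLASGGPSRDVSEPQLLGCTCEPGEIHGALPVPPCQIGAKTPSRYHMYSTNGPESSPCYGMVNERFILTADCQCGCIVLKPATLAVCRRLFSLNRLAPCALKLSVRLREKVTRHVVRCCSTRVLCGFSKTSTLSFPSLLEEVD
>sp3_er
SALQRKTNYSGIGPFKNGRVEIIADQVTNFIRTSNDTQLRRNKTKAEAIAVPLFYLPGLASGGPSRDVSEPQRLGCTCEPGEIHVALPVTPWQIGAKTPSRYHMYSTNGPESSRCYGMLNERFILTADCQWGFIVFKPATVAVCRRLFSLNRLARFALKLSVRLREMVTRHVVGCCSTRVLCGLSKTSTLSFPSLLKDEL
>sp3_mt
SALQRKTNNSGIAPMEGKTPKVLEAEVTSFTRTSKDTQLRRNKTKGEAIAVPLFYLPGLASGGPSRDVSEPQRLGCTCEPGEIHGALPVPPCQIGAKTPSRYHMYSTNGPESSRCYGMLNERFILTADCQWGCIVLRPATVAVCRRLFSPNRLPPFALKLSVRLREMVTRHVVGCCSTRVLCGLSKTSTLSFPSLLGSSA
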