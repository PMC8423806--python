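>sp1_cA
FALEKKTNYSGIGPFQHGKVEIIADQVTNFTRTSNDTKLRAYKSKGVAIAVLLFYFPGLAPGGPSSDVSEPQRLGYTCEPGQIHGALTVPPCLIGAKTPSSRYHMYSPNRPESSRCYGMVNVRFMLTADCQWGCIVLEPATVAACRQLFSINCLAPVALNLSVQLRKVFTRHVAGCCSTRVLCGLAKTTTMSFPNLLEEVD
>sp1_cB
SAVQQKTNYSGIGPFQHGKVEIIADQVTNFTRTSHDIQLRGNKTKGEAIAVPLFYLPGLASGGPSRDVSEPQRLGCTCEPGEIHGALPVPPCQIGAKTPS-RYHMYSTNGPESSRCYGMVNERFILTADCQWGCIVLKPATLAVCRRLFSLNLLAPCALKQSVRPREKVTRHVVRCCSTRVLCGFSKTSTLSFPSLLEEVD
>sp1_er
SALQRQTNYSGIGPFKNGRVEIIADQVTNFIRTSNDTQLRRNKTKAEAIAVSLFYFPGLASGGPSRDVSEPQRLGCTCEPGEIHVALPVTPWQIGAKTPS-RYHMYSTNGPESSRCYGMLNERFILTADCQWGFIVLKPATVAVWRRLFSLNRLAPFALKLSVRLREMVTRHVVGCCSTRVLCGLSKTSTLSFPSLLKDEL
>sp1_mt
SALQRKTNNSGIAPMEGKTPKVLEAEVTSFTRTSNDTQLRRNKTKGEAIAVPLFYLPGLASGGPSRDVSEPQRLGCTCEPGEIHGALPVPPWQIGAKTPS-RYHMYSTNGPESSRCYGMLNERFILTADCQWGCIVLKPATVAVCRRLFSLNRLAPFALKLTVRLREMVTRHVVGCYSTRVLCGLSKTSTLSFPSLLGSSA
>sp2_cA
FELQQKTNYSGIGPFQHGKVEIIADQVTNFTRTSNDTKLRGYTSKGEAIAVPLFYLPGLASGGPSRDVSEPQRLEDSCEPGEIQGAPTVPPCLIGAKTPSSRYHMYSSNRPVSSRCYGMVYERFILTADCQWGCIVLKPAKLAACQQLFSMNCLAPFALKLSVRLRKMVTRHVAGCYSTRVLCGLAKTSTLSFPSLLEEVD
>sp2_cB
SAVQQKTNYSGIGPFQHGKVEIIADQVTNFTRTSNDIQLRGNKTKGEAIAVPLFYLPGLASGGPSRDVSEPQRLGCTCEPGEIHGALPVPPCQIGAKTPS-RYHMYSTNGPESSRCYGMVNERFILTADCQWGCIVLKPATLAVCRRLFSLNRLAPCALKLSVRLREMVTRHVVRCCSTRVLCGLSKTSTLSFPSLLEEVD
>sp2_er
SALQRKTNYSGIGPFKNGRVEIIADQVTNFIRTSNDTQFRRNKTKAEAIAVPLFYLPGLASGGPSRDVSKPQRLGCTCEPGEIHVALPVTPWQIGAKTPS-RYHMYSTNGPESSRCYGMLNEPFILTADCQWGFIVLKPATVAVCRRLFSLNRLAPFALKLSVRLREMVTRHVVGCCTTRVLCGLSRTSTLSFPSLLKDEL
>sp2_mt
SALQRKTNNSGIAPMEGKTPKVLEAEVTSFTRTSKDTQLRRNKTKGEAIAVPLFYLPGLASGGPSRDVSEPQRLGCTCEPGEIHGALPVPPCQIGAKTPS-RYHMYSTNGPESSRCYGMLNERFILTADCQWGCIVLKPATVAVCRRLFSLNRLAPFALKLSVGLREMVTRHVVGCCSTRVLCGLSKTSTLSFPSLLGSSA
>sp3_cA
FALQQKTNYSGIGPFQHGKVEIIADQVTNFTRTSNDTKLRGNKSKGEAIAVPLFYLLGLASGGPSRDVSEPRRLGDSCEPGHILGAVTVPPCLIGAKTPSSRYHMYYSNRPESSWCYGMVYERFILTADCQWGCIVLKPATLAACRQLFSMNCLAPFAFKLSVRMRKMVTRHVAGCYSRRVLCGLAKTSTLSFPRLLEEVD
>sp3_cB
SAVQQKTNYSGIGPFQHGKVEIIADQVTNFTRTSNDIQLRGNKTKGEAIAVPLFYLPGLASGGPSRDVSEPQLLGCTCEPGEIHGALPVPPCQIGAKTPS-RYHMYSTNGPESSPCYGMVNERFILTADCQCGCIVLKPATLAVCRRLFSLNRLAPCALKLSVRLREKVTRHVVRCCSTRVLCGFSKTSTLSFPSLLEEVD
>sp3_er
SALQRKTNYSGIGPFKNGRVEIIADQVTNFIRTSNDTQLRRNKTKAEAIAVPLFYLPGLASGGPSRDVSEPQRLGCTCEPGEIHVALPVTPWQIGAKTPS-RYHMYSTNGPESSRCYGMLNERFILTADCQWGFIVFKPATVAVCRRLFSLNRLARFALKLSVRLREMVTRHVVGCCSTRVLCGLSKTSTLSFPSLLKDEL
>sp3_mt
SALQRKTNNSGIAPMEGKTPKVLEAEVTSFTRTSKDTQLRRNKTKGEAIAVPLFYLPGLASGGPSRDVSEPQRLGCTCEPGEIHGALPVPPCQIGAKTPS-RYHMYSTNGPESSRCYGMLNERFILTADCQWGCIVLRPATVAVCRRLFSPNRLPPFALKLSVRLREMVTRHVVGCCSTRVLCGLSKTSTLSFPSLLGSSA
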