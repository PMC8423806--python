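>sp1_cA
TTTGCCCTCGAAAAGAAGACAAACTACAGCGGAATAGGACCATTCCAACACGGAAAAGTAGAAATAATAGCAGACCAAGTAACAAACTTCACAAGGACCTCAAACGACACAAAGCTGCGCGCGTATAAATCTAAAGGAGTGGCTATAGCCGTGCTGCTCTTTTACTTTCCCGGCTTAGCTCCTGGAGGGCCATCTAGTGATGTATCCGAGCCTCAGCGGCTTGGGTACACATGTGAGCCGGGACAGATTCATGGTGCTCTGACCGTGCCTCCTTGCCTAATCGGTGCGAAGACCCCTTCAAGCCGATACCATATGTACTCACCCAATAGACCGGAGAGTTCGCGGTGCTATGGCATGGTGAATGTGCGATTCATGTTAACCGCAGATTGCCAGTGGGGATGTATAGTATTGGAGCCGGCGACGGTTGCGGCTTGTAGACAGCTCTTCAGTATTAATTGCCTAGCCCCGGTTGCTTTAAATCTTTCAGTGCAACTGAGAAAAGTATTTACACGCCACGTAGCAGGTTGTTGTAGTACGAGAGTATTGTGCGGATTGGCTAAAACTACCACCATGTCATTCCCCAATCTCTTGGAAGAAGTAGACTAA
>sp1_cB
TCAGCGGTGCAACAGAAGACAAACTACAGCGGAATAGGACCATTCCAACACGGAAAAGTAGAAATAATAGCAGACCAAGTAACAAACTTCACAAGGACCTCGCACGACATACAGCTCCGGGGAAACAAGACTAAAGGCGAAGCAATTGCTGTACCTCTCTTTTACTTGCCAGGTTTAGCTTCTGGCGGGCCATCTAGAGATGTGTCCGAACCGCAGCGTCTGGGGTGCACTTGTGAACCGGGCGAGATTCATGGAGCTCTGCCAGTACCCCCGTGTCAAATCGGTGCGAAGACCCCTTCACGATACCATATGTACTCAACAAATGGACCCGAAAGTTCGCGTTGCTACGGTATGGTGAATGAGCGCTTTATCCTAACAGCGGATTGCCAGTGGGGTTGTATAGTGTTAAAGCCTGCGACGCTTGCTGTTTGTCGACGGCTTTTCAGTCTGAACCTACTAGCCCCCTGTGCATTAAAACAATCAGTCCGCCCACGCGAAAAAGTTACACGTCACGTAGTGCGTTGCTGTAGCACTAGAGTGTTGTGTGGATTTTCCAAAACATCGACCTTGTCGTTCCCCAGCCTGTTGGAAGAAGTAGACTAA
>sp1_er
TCCGCCCTTCAACGGCAGACAAACTACAGCGGAATAGGACCATTCAAAAACGGAAGAGTAGAAATAATAGCAGACCAAGTAACAAACTTCATAAGGACCTCGAACGACACACAACTGCGGCGCAATAAGACTAAAGCGGAAGCTATCGCCGTTTCTCTATTTTATTTTCCTGGTTTAGCTTCAGGTGGGCCGTCTAGAGATGTATCCGAACCGCAGAGACTGGGTTGTACATGTGAACCCGGAGAGATTCACGTTGCGCTGCCAGTGACTCCATGGCAAATCGGTGCGAAGACCCCTTCACGATACCATATGTACTCTACAAATGGCCCAGAGAGCTCGCGTTGTTACGGCATGCTGAATGAGCGGTTTATACTAACGGCAGATTGTCAGTGGGGATTCATAGTGCTAAAGCCGGCGACCGTCGCGGTCTGGCGACGGCTGTTCAGTCTGAATCGCTTAGCCCCCTTTGCCTTAAAACTTTCTGTGAGACTCCGCGAGATGGTAACACGCCACGTAGTCGGCTGTTGTAGTACAAGGGTGTTGTGTGGACTGTCCAAAACTTCGACATTGTCATTCCCCAGCCTTTTGAAAGACGAACTATAA
>sp1_mt
TCTGCTCTTCAACGGAAGACAAACAACAGCGGAATAGCACCAATGGAAGGAAAAACACCAAAAGTACTAGAAGCAGAAGTAACAAGCTTCACAAGGACCTCGAACGACACACAGCTCCGCCGAAACAAAACCAAGGGAGAAGCAATCGCCGTGCCTTTGTTTTACTTGCCGGGACTGGCCTCAGGCGGGCCATCTAGAGATGTATCGGAACCTCAGAGACTCGGCTGCACATGTGAACCCGGCGAGATACACGGAGCATTACCAGTGCCACCTTGGCAAATTGGTGCGAAGACCCCTTCACGATACCATATGTACTCTACAAATGGCCCTGAGAGTTCTCGGTGTTACGGCATGCTGAATGAGCGATTTATACTAACAGCGGATTGCCAGTGGGGATGTATAGTGTTAAAGCCCGCGACGGTCGCTGTGTGTCGACGCTTGTTCAGTCTGAATCGCCTAGCACCCTTTGCCTTAAAACTAACAGTGCGACTGCGCGAGATGGTTACGCGACACGTGGTTGGATGTTATAGTACTAGAGTGTTGTGTGGATTGTCCAAAACTTCGACATTGTCATTCCCCAGCCTATTGGGAAGCAGCGCATAA
>sp2_cA
TTTGAGCTGCAGCAGAAAACAAACTACAGCGGAATAGGACCATTCCAACACGGAAAAGTAGAAATAATAGCAGACCAAGTAACAAACTTCACAAGGACCTCGAACGACACAAAGCTGCGCGGATATACCTCCAAAGGAGAAGCGATTGCCGTGCCGCTCTTCTACTTGCCTGGCCTAGCTTCTGGCGGGCCCTCTAGAGATGTATCGGAACCGCAGCGGCTGGAGGACTCATGTGAGCCGGGTGAAATTCAAGGTGCTCCGACCGTGCCTCCCTGCTTAATCGGTGCGAAGACCCCTTCAAGCCGATACCATATGTACTCTAGTAATCGACCCGTGAGTTCGCGGTGTTATGGCATGGTTTATGAGCGATTCATCCTAACCGCGGATTGCCAGTGGGGATGTATAGTTTTGAAGCCGGCGAAGCTTGCGGCCTGTCAACAACTCTTCAGCATGAACTGCCTTGCGCCGTTTGCATTAAAACTATCAGTGCGATTGCGAAAAATGGTTACACGCCACGTAGCGGGTTGTTATAGCACAAGAGTTTTGTGCGGATTGGCTAAAACTTCCACCTTGTCATTCCCCAGCCTTTTGGAAGAAGTAGACTAA
>sp2_cB
TCGGCGGTGCAACAGAAGACAAACTACAGCGGAATAGGACCATTCCAACACGGAAAAGTAGAAATAATAGCAGACCAAGTAACAAACTTCACAAGGACTTCGAACGACATCCAGCTCCGCGGAAACAAAACTAAAGGGGAAGCAATTGCTGTGCCTCTCTTTTACTTGCCTGGTCTAGCGTCTGGCGGGCCGTCCAGAGATGTGTCCGAACCGCAGCGCCTAGGGTGCACCTGTGAACCGGGCGAGATTCACGGCGCTTTGCCAGTGCCGCCATGCCAAATTGGTGCGAAGACCCCTTCACGATACCATATGTACTCTACAAATGGACCGGAGAGTTCCCGTTGCTACGGTATGGTAAATGAGAGATTTATCTTAACTGCTGATTGCCAGTGGGGTTGTATAGTGCTAAAGCCTGCGACCCTCGCAGTCTGTCGAAGGCTATTCAGTCTAAATCGCCTTGCCCCCTGTGCATTAAAACTATCAGTGCGCCTGCGCGAAATGGTAACACGACACGTGGTGCGTTGCTGTAGCACTAGAGTGTTGTGTGGATTGTCTAAAACTTCCACTTTGTCTTTCCCCAGCCTTTTGGAAGAAGTAGACTAA
>sp2_er
TCAGCTCTCCAACGGAAGACAAACTACAGCGGAATAGGACCATTCAAAAACGGAAGAGTAGAAATAATAGCAGACCAAGTAACAAACTTCATAAGGACCTCTAACGACACTCAATTCCGCCGAAACAAGACTAAAGCCGAAGCCATCGCCGTTCCTCTCTTTTATTTGCCTGGATTAGCTTCCGGTGGGCCATCCAGAGATGTATCCAAACCGCAACGGCTGGGTTGCACTTGTGAACCTGGCGAGATACACGTTGCACTGCCAGTGACTCCATGGCAAATCGGTGCGAAGACCCCTTCACGATACCATATGTACTCTACTAACGGCCCAGAGAGCTCACGCTGTTACGGTATGCTGAATGAGCCGTTTATTTTAACCGCGGATTGTCAGTGGGGATTCATAGTTCTAAAGCCGGCGACAGTGGCGGTGTGTCGACGGCTGTTCAGTCTGAATCGCTTAGCACCCTTCGCATTAAAACTTTCTGTTAGACTACGCGAGATGGTTACGCGCCACGTAGTCGGTTGTTGTACTACTAGGGTGTTGTGTGGACTATCGAGAACTTCGACGTTGTCGTTCCCCAGCCTTTTAAAAGACGAACTATAA
>sp2_mt
TCTGCACTCCAACGTAAGACTAACAACAGCGGAATAGCACCAATGGAAGGAAAAACACCAAAAGTACTAGAAGCAGAAGTAACAAGCTTCACAAGGACCTCGAAAGACACACAGCTGCGCCGAAACAAAACTAAAGGCGAAGCTATCGCCGTGCCTCTCTTTTACTTGCCGGGATTAGCCTCCGGCGGACCATCGAGGGATGTATCGGAACCTCAACGACTCGGCTGTACATGTGAACCCGGTGAGATACACGGTGCATTGCCGGTGCCGCCATGCCAAATCGGTGCGAAGACCCCTTCACGATACCATATGTACTCTACTAATGGGCCAGAGAGCTCACGTTGCTACGGCATGCTGAATGAGCGATTTATTTTAACAGCGGATTGCCAGTGGGGGTGCATTGTGCTAAAACCGGCGACGGTCGCTGTGTGTAGACGGCTGTTTAGTCTGAATCGCTTAGCACCCTTTGCGTTAAAACTTTCAGTGGGACTGCGCGAGATGGTTACACGACACGTGGTTGGTTGCTGTAGTACTAGAGTGTTGTGTGGATTGTCCAAAACGTCCACATTGTCATTCCCCAGCCTATTGGGAAGCAGCGCATAA
>sp3_cA
TTTGCGCTGCAACAGAAAACAAACTACAGCGGAATAGGACCATTCCAACACGGAAAAGTAGAAATAATAGCAGACCAAGTAACAAACTTCACAAGGACCTCCAACGACACAAAGCTGCGCGGAAATAAATCCAAAGGAGAAGCCATTGCCGTGCCGCTCTTCTACTTGCTTGGCCTAGCTTCTGGGGGGCCATCGAGAGATGTATCGGAACCACGGCGGCTGGGGGACTCATGTGAGCCAGGTCACATTCTTGGTGCTGTGACCGTGCCTCCATGCCTTATCGGTGCGAAGACCCCTTCAAGCCGATACCATATGTACTACAGTAATAGACCGGAGAGTTCGTGGTGCTATGGAATGGTGTATGAGCGATTCATCTTAACCGCCGATTGCCAATGGGGGTGTATAGTTTTAAAGCCGGCGACGCTTGCGGCCTGTAGACAGCTCTTCAGCATGAATTGCCTGGCTCCCTTTGCTTTTAAACTATCAGTTCGAATGCGAAAAATGGTTACACGCCACGTAGCGGGTTGTTATAGCAGAAGAGTGTTGTGCGGATTGGCTAAAACATCCACCCTGTCATTCCCCAGGCTTTTGGAAGAAGTAGACTAA
>sp3_cB
TCGGCGGTGCAACAGAAGACAAACTACAGCGGAATAGGACCATTCCAACACGGAAAAGTAGAAATAATAGCAGACCAAGTAACAAACTTCACACGGACCTCGAACGACATACAGCTCCGCGGAAACAAAACTAAAGGGGAAGCAATCGCTGTGCCACTATTTTACTTGCCAGGATTAGCATCTGGCGGGCCATCTAGAGATGTGTCCGAACCGCAGCTTCTCGGGTGCACTTGTGAACCAGGCGAGATACATGGAGCTCTGCCAGTACCTCCGTGTCAAATCGGTGCGAAGACCCCTTCACGATACCATATGTACTCTACAAATGGTCCGGAAAGTTCGCCTTGCTACGGTATGGTGAATGAGAGATTTATCCTAACAGCGGATTGCCAGTGTGGTTGTATAGTGTTGAAGCCTGCGACACTTGCAGTGTGTCGACGGCTTTTCAGTCTGAACCGACTAGCCCCCTGTGCATTAAAACTATCAGTCCGCTTACGCGAAAAGGTTACACGGCACGTAGTTCGGTGCTGTAGCACTAGGGTGTTATGTGGATTCTCTAAAACTTCCACCTTGTCGTTCCCCAGCCTTTTGGAAGAAGTAGACTAA
>sp3_er
TCCGCCCTGCAACGGAAGACAAACTACAGCGGAATAGGACCATTCAAAAACGGAAGAGTAGAAATAATAGCAGACCAAGTAACAAACTTCATAAGGACCTCGAACGACACTCAACTCCGTAGAAACAAGACTAAAGCCGAAGCGATCGCCGTTCCCCTATTTTATTTGCCTGGATTAGCTTCCGGTGGGCCATCCAGGGATGTATCCGAACCGCAACGACTGGGGTGCACATGTGAACCTGGCGAGATACACGTTGCACTGCCAGTGACTCCATGGCAAATCGGTGCGAAGACCCCTTCACGATACCATATGTACTCTACAAATGGCCCCGAGAGCTCGCGCTGTTACGGTATGCTGAATGAGCGATTTATTTTAACTGCGGATTGCCAGTGGGGATTCATAGTTTTTAAGCCTGCGACCGTGGCGGTGTGTCGACGGCTTTTCAGTCTGAATCGCTTAGCACGCTTCGCATTAAAACTTTCTGTGAGACTACGCGAGATGGTTACACGCCACGTAGTCGGTTGTTGTAGTACTAGGGTGTTGTGTGGACTATCTAAAACTTCCACATTGTCGTTCCCCAGCCTTTTGAAAGACGAACTATAA
>sp3_mt
TCTGCACTCCAACGTAAGACTAACAACAGCGGAATAGCACCAATGGAAGGAAAAACACCAAAAGTACTAGAAGCAGAAGTAACAAGCTTCACAAGGACCTCGAAAGACACACAGCTGCGCCGAAACAAAACTAAGGGCGAAGCTATCGCCGTGCCGCTCTTCTACTTGCCGGGTTTAGCCTCCGGCGGGCCATCTAGAGATGTATCGGAACCTCAACGACTCGGCTGTACATGTGAACCCGGTGAGATACACGGCGCATTGCCTGTGCCACCATGCCAAATCGGCGCGAAGACCCCTTCACGATACCATATGTACTCTACAAATGGGCCAGAGAGCTCACGTTGTTACGGCATGCTAAATGAACGCTTTATTCTAACAGCGGATTGCCAGTGGGGGTGCATTGTACTAAGGCCGGCGACGGTCGCTGTGTGTCGACGGCTGTTTAGTCCGAATCGCTTACCACCGTTTGCGTTAAAACTGTCAGTGCGACTGCGCGAGATGGTCACGAGACATGTGGTTGGTTGCTGTAGTACGAGAGTCTTGTGTGGATTGTCCAAAACTTCGACATTGTCGTTCCCCAGCCTATTGGGAAGCAGCGCATAA
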