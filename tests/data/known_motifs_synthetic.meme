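MEME version 4

ALPHABET= ACGT

strands: + -

Background letter frequencies
A 0.25000 C 0.25000 G 0.25000 T 0.25000

MOTIF SYN_PITX1
letter-probability matrix: alength= 4 w= 14 nsites= 20 E= 0
0.006130 0.957486 0.017948 0.018436
0.024044 0.948502 0.016408 0.011046
0.033154 0.921855 0.015708 0.029283
0.027405 0.003490 0.033810 0.935296
0.020272 0.950078 0.027485 0.002165
0.021383 0.009452 0.013683 0.955483
0.001473 0.969025 0.014205 0.015297
0.010848 0.949470 0.013527 0.026154
0.958881 0.011484 0.011194 0.018441
0.011443 0.943052 0.004643 0.040863
0.028682 0.831214 0.048493 0.091611
0.019098 0.005601 0.954177 0.021124
0.021954 0.034313 0.934652 0.009080
0.018767 0.011164 0.943830 0.026239

MOTIF SYN_RARA
letter-probability matrix: alength= 4 w= 15 nsites= 20 E= 0
0.971950 0.010843 0.005371 0.011836
0.018977 0.006048 0.967116 0.007859
0.035809 0.021362 0.018302 0.924527
0.028685 0.040706 0.002291 0.928318
0.018873 0.947679 0.009123 0.024325
0.949024 0.024395 0.014514 0.012066
0.011241 0.014082 0.944243 0.030434
0.957403 0.021794 0.003291 0.017512
0.952490 0.021027 0.014737 0.011746
0.020451 0.013275 0.962114 0.004159
0.027229 0.949895 0.017182 0.005694
0.015127 0.947657 0.008599 0.028617
0.008934 0.006237 0.003950 0.980879
0.025194 0.952021 0.008916 0.013869
0.025019 0.025162 0.033374 0.916445

MOTIF SYN_FOXF1
letter-probability matrix: alength= 4 w= 10 nsites= 20 E= 0
0.001309 0.953372 0.007915 0.037404
0.940203 0.010799 0.027846 0.021151
0.015968 0.936321 0.036002 0.011710
0.005977 0.012040 0.018170 0.963813
0.021511 0.912433 0.018815 0.047242
0.000992 0.028062 0.959353 0.011594
0.932621 0.020411 0.019347 0.027621
0.024269 0.017206 0.930801 0.027724
0.008260 0.020587 0.944869 0.026285
0.017241 0.021459 0.955535 0.005765

MOTIF SYN_FOXA1
letter-probability matrix: alength= 4 w= 14 nsites= 20 E= 0
0.945564 0.009903 0.002126 0.042407
0.004345 0.003232 0.983630 0.008793
0.003615 0.977330 0.011947 0.007109
0.036123 0.006484 0.932199 0.025194
0.024080 0.013984 0.954575 0.007362
0.014137 0.001332 0.006710 0.977821
0.058148 0.011212 0.007834 0.922806
0.006940 0.005697 0.982163 0.005200
0.024978 0.919585 0.034351 0.021086
0.023127 0.019779 0.009533 0.947560
0.004965 0.002318 0.014755 0.977962
0.029143 0.925891 0.039062 0.005904
0.922033 0.036497 0.010759 0.030710
0.017177 0.021176 0.024163 0.937484

MOTIF SYN_BHLHE41
letter-probability matrix: alength= 4 w= 12 nsites= 20 E= 0
0.953410 0.022279 0.020636 0.003675
0.004771 0.015381 0.973392 0.006457
0.026130 0.002952 0.004028 0.966890
0.017549 0.025542 0.004187 0.952722
0.019457 0.034185 0.004321 0.942036
0.010688 0.017985 0.964472 0.006855
0.007870 0.040990 0.012859 0.938281
0.013366 0.010359 0.044971 0.931303
0.948013 0.022483 0.010775 0.018729
0.010249 0.017272 0.954696 0.017783
0.035905 0.918050 0.013897 0.032148
0.026987 0.007088 0.013660 0.952264

MOTIF SYN_BHLHE40
letter-probability matrix: alength= 4 w= 10 nsites= 20 E= 0
0.022949 0.028004 0.010157 0.938890
0.090641 0.872770 0.024003 0.012586
0.012274 0.006554 0.975248 0.005923
0.000801 0.006952 0.977973 0.014273
0.974669 0.002612 0.009646 0.013073
0.914534 0.064636 0.006993 0.013838
0.003128 0.052743 0.920213 0.023916
0.010726 0.968489 0.003220 0.017565
0.012099 0.973423 0.012079 0.002399
0.028401 0.031691 0.927141 0.012767

MOTIF SYN_TFAP2C
letter-probability matrix: alength= 4 w= 10 nsites= 20 E= 0
0.952724 0.012593 0.032687 0.001996
0.962601 0.003792 0.018821 0.014785
0.017414 0.942052 0.027155 0.013379
0.971992 0.012786 0.005537 0.009685
0.937132 0.016422 0.031658 0.014788
0.937582 0.002802 0.053322 0.006294
0.967566 0.004376 0.005225 0.022833
0.016261 0.003885 0.971817 0.008037
0.024885 0.016282 0.945265 0.013568
0.912155 0.027199 0.012071 0.048574

MOTIF SYN_RUNX1
letter-probability matrix: alength= 4 w= 14 nsites= 20 E= 0
0.961765 0.010195 0.008769 0.019270
0.021438 0.023815 0.024429 0.930318
0.007113 0.983234 0.006952 0.002702
0.938839 0.030993 0.004664 0.025504
0.944868 0.008432 0.034440 0.012259
0.035488 0.949794 0.004894 0.009824
0.035314 0.021143 0.926995 0.016548
0.936086 0.044146 0.007192 0.012575
0.007410 0.012870 0.936159 0.043561
0.941319 0.025650 0.029030 0.004001
0.008736 0.006850 0.024920 0.959494
0.945855 0.007375 0.026299 0.020471
0.004106 0.022300 0.024014 0.949581
0.006812 0.953383 0.012153 0.027652

MOTIF SYN_MYCMAX
letter-probability matrix: alength= 4 w= 14 nsites= 20 E= 0
0.015469 0.078901 0.891821 0.013809
0.050216 0.929347 0.000521 0.019916
0.983283 0.000873 0.010058 0.005786
0.021717 0.002695 0.934029 0.041558
0.011647 0.028367 0.005650 0.954336
0.005487 0.955591 0.024899 0.014023
0.029868 0.002321 0.014746 0.953066
0.006384 0.006907 0.953266 0.033443
0.023366 0.001667 0.963824 0.011144
0.012210 0.063092 0.013951 0.910747
0.023500 0.951254 0.024003 0.001242
0.913743 0.022603 0.012480 0.051174
0.018754 0.006822 0.964562 0.009862
0.028726 0.039711 0.001128 0.930435

MOTIF SYN_CTCF
letter-probability matrix: alength= 4 w= 13 nsites= 20 E= 0
0.004322 0.029640 0.957136 0.008903
0.012459 0.002300 0.978399 0.006842
0.009312 0.059407 0.028563 0.902717
0.065536 0.893247 0.036644 0.004572
0.006837 0.025763 0.009371 0.958029
0.011839 0.928112 0.027029 0.033020
0.018864 0.019034 0.035433 0.926670
0.008999 0.896085 0.082371 0.012546
0.020202 0.950350 0.018849 0.010598
0.015359 0.015620 0.012686 0.956334
0.004703 0.017726 0.963216 0.014355
0.969459 0.000687 0.013806 0.016048
0.005621 0.043358 0.932104 0.018918

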