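accession	fingerprint
Irwin	35667755562411133444242411264555
Apple	25687715364414112311232533253655
Nam Doc Mai	24444555161225231315345615164445
Chishu	25464558132315343435243588465666
Arumanis B	25454655562644343344342336243635
JinHuang	45341555132445232355334615264635
Tainong No. 1	34451155161424133444254558124656
kyo savoy	25681118113355333434222518465646
Renong No. 1	36661613132212113444232215256656
Kent	35347715152424332315344518226635
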