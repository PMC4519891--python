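1atpi
1cdlg
1edn-
1bpha
2mltb
1mcti
1coi-
9insb
2mhu-
1dfnb
1mrt-
1gcmc
1cbh-
1ppt-
1tabi
1tiic
9apib
1wfbb
4cpai
1edmc
4rhv4
2erl-
1fc2c
1htrp
1bds
1crn
2ltnb
1sh1
6hir
1ptr
4sgbi
1hcgb
1hcra
1mof
4rxn
1ovoa
1pga
2mev4
2tgpi
1cdta
1rpo
1isub
1csei
2or1l
1ptx
1wapv
1ctf
1mjc
1bovb
2utga
1il8a
2hipb
1spbp
4fisb
1latb
3ait
1hyp
3icb
1ubq
1tif
1vcc
1cksc
1bdo-
1cc5
1pht
1lpba
2bopa
1cei
1hip
1brse
2hpr
1aazb
2gn5
1lmb3
1tig
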