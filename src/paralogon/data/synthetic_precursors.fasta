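>PENK_synthetic synthetic stand-in, planted motif architecture
SESNTHVECMTIMCQSDVQDCLHDCIPDIECTDCNCNTHIPPSEHKRYGGFMKRHWQITW
QPLCKRYGGFMKRMSNTQIVNLQAIHQKRYGGFMKKAQSMNCIETHPIASCQDETSVPKR
YGGFMKRPMQLVMEPKRYGGFLKRICQHSQMEQLSMPPNSCENIHNLNTWKRYGGFMRRN
ILESQVNHASQKRYGGFMMT
>PDYN_synthetic synthetic stand-in, planted motif architecture
VVHDQVCWHEHECNHLIICSCEICMNTWVTNWTNECACHAWPKRSGGFLPHSSACLAITL
CKRAGGFMNEWTDWCVHSADNLCWKRYGGFLRKLPQNPSMPMCKRYGGFLRRDWSLAPEH
IANHENPSMPKRYGGFLRRDEWCQHHAQI
>PNOC_synthetic synthetic stand-in, planted motif architecture
SSPCHCPCEPSMCNNATNWDSACIEWCEDNWTSNNVEWTPPPIKRPHLSTNISDDQDSTS
IDKRFGGFIILQMLNVDTWTSKRNSIVCHMTQI
>POMC_synthetic synthetic stand-in, planted motif architecture
ECDMSSDTACINNCAALSSTNACSPHICMVDHQECSLEWVMSKRALSVVHFRWDLQVPNK
RIHWCIEDDLCEEMITSKREATDDLHFRWENTTQVMDTKRASSLVETWIQWEHNQQASAL
KRVTWLHFRWAWEWHKKPEHSWCKRYGGFMSNNQHLAEQAHAATDDPIVLINIP
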