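>synthetic_001 synthetic training window seed=1002
ASASAGNDHRQGRDKEEQGRDNRQK
>synthetic_002 synthetic training window seed=1002
ASAIAGNDEEQRRQKHNQGKHNNQK
>synthetic_003 synthetic training window seed=1002
ASAAPGEDHQENNDNKNDHDGHEQK
>synthetic_004 synthetic training window seed=1002
SLASFGNDKHGGQKKNRQGKQDEQK
>synthetic_005 synthetic training window seed=1002
VSASAGKQDHDKNDKNEQEKHNQQG
>synthetic_006 synthetic training window seed=1002
AMAPAGRDDEQGNKGQHQGGKGREK
>synthetic_007 synthetic training window seed=1002
ASASYGNHKHGGNDQHREGGNGDGH
>synthetic_008 synthetic training window seed=1002
MSAMARNGRGNGHGKNGEDDDQKHN
>synthetic_009 synthetic training window seed=1002
FVASAGNDEGEGNQEREQQNGKDND
>synthetic_010 synthetic training window seed=1002
ASAAAGNNNGGGNGNHQQGQDNEGR
>synthetic_011 synthetic training window seed=1002
AYASAGNDKHKGNRQRQDGKQQDRD
>synthetic_012 synthetic training window seed=1002
PFASAGQHREDQQDKHKREKDQDQR
>synthetic_013 synthetic training window seed=1002
SSASAGGDHKGGNDKHERGKNNEDK
>synthetic_014 synthetic training window seed=1002
LSAWPGKDQEHGNDKHRDEHDQDQK
>synthetic_015 synthetic training window seed=1002
ISASAGNNRHKGNKKGEQQKDRQQK
>synthetic_016 synthetic training window seed=1002
AVASAGNEKEGQNDKHEKGKRDEQK
>synthetic_017 synthetic training window seed=1002
ATAAAGEDDRQEEDKDDQNKEKNQQ
>synthetic_018 synthetic training window seed=1002
SFAVAGNDDEDGNGHHEGNRHNEQG
>synthetic_019 synthetic training window seed=1002
PSASAGNRHHQGNDKQEEGKDNGHK
>synthetic_020 synthetic training window seed=1002
AWAMAGGDKEQDNDEGGQQQGDEQE
>synthetic_021 synthetic training window seed=1002
VSASAGRDHKQNKNKHKHGRRNEQH
>synthetic_022 synthetic training window seed=1002
AVASARDDDEQRHGNRHQGNDDRQD
>synthetic_023 synthetic training window seed=1002
WSMPAGNQDEEKEQKNEQGNDRERK
>synthetic_024 synthetic training window seed=1002
ASASAGNDKNHGQDKGRNEKNNENN
>synthetic_025 synthetic training window seed=1002
AAATAGNNKEQNENRREGGKDDDQK
>synthetic_026 synthetic training window seed=1002
AVAPVGGHKGNGQHQHEHGDDKEGQ
>synthetic_027 synthetic training window seed=1002
ASAYAGEDQGNHHDKHNEDKKNKQK
>synthetic_028 synthetic training window seed=1002
VYAPAGNEHEDQDHGDGHEKDNGEQ
>synthetic_029 synthetic training window seed=1002
LSASAGDKDEQQNDNHRDGHENGQD
>synthetic_030 synthetic training window seed=1002
ASASAGNRGEQNQKKDDRRGEKKQK
>synthetic_031 synthetic training window seed=1002
AMASAGNDKRDGKQKHEEKKDNGQD
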