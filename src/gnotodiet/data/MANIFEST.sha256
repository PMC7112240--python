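1b94a22295cfe1d5e3c43ab7845dcde5d5cada0e61b7ef48591855be9731ff98  compounds.tsv
b0e9f37cb0b37f7de57cbce78e5fe2cefff91b14bd6c71e3f60a1607b7f1d47f  flyaa_medium.tsv
17e881b14929844bbdcdc5ce4bfcca9ae7d255b11881ecda071af1967b6df5b1  phenotypes.csv
5a91cbe5e4d18007a302aebe05a886fec51b00577d0062e9f8dd9dc75723ede3  producibility.csv
9bc604ac2a0fa2d0daf0c10393490d55d08ddf319ed5dbb9d809584fede36925  reactions_ap.tsv
d47f9e5695b68dcf4b40fa5619b4e389ae12cfc4255dcf007468f97702db9134  reactions_dmel.tsv
23a06986decc080f5d899906684279db18e5d62ca893b2c3fe832706af677b2d  reactions_lp.tsv
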