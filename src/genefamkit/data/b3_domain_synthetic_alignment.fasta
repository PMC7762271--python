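>B3_synth_01
EMERSDPDKCSGLMTPVYPVGITGYQFDMFYANRLGPGLLAYKKIFHKYDAMWDQNIPGY
DNLLKYWFEFCCACPIHKAL
>B3_synth_02
EMERSDPRGCSALMTPVYPVGITGYQFDMFYANRLGPGLLAQKKIFFKYDWMWNMNIPGD
DNALFYNFVYCCACPIHKAL
>B3_synth_03
EMERSDPRCPSKLMKPVYPSGITGYQFDMMYANRLGPGLLAQKKKFFKYVWMWCGNIPGY
DNALFYWFVYCCARPIHKAY
>B3_synth_04
EMERSDPRCCSKLMTPVYPVGITGYQFDMFYANRLGPGLQAQKKGFFKYAWKWDGNIPGY
DNALFYWFVYCCAIPIHKAL
>B3_synth_05
EMERSCPRCCSKLMTPVYPVGITGYQFDMFYANRLGPGLLAQVKIFHKYDWMWSGNIPGY
DNALFYMFVYCCACPIHKAL
>B3_synth_06
EMWRSDPRCCSKLMTPVYPVGITGYQFDMFLANRLGPGLLAQKKIFFKYDWMWDGNIPGY
DNALFYWFQYCCACEIHQAL
>B3_synth_07
EMERSDPCCCSKLMTPVYPVGITGYQFDMFYANRPGPGLLAQKKIFFKYDWMWDGNVPGG
DNALFYWFVYHCACPIHKAL
>B3_synth_08
EMERSDPRCCSKGMTPVYPVGITGYQFDMFYAARLHGGLLAQKKIFFKYDWMWQGNKPGY
DNALFYWFVYCCQDPIHKAK
>B3_synth_09
EMERSDPRCCSKLMTPFYVVGITGYQFDMRYANRLGPGLLAQKKIFFNYDWMWDGNIFGY
DNALFIKFVYCCVCPIHKAL
>B3_synth_10
EMNRSDPRCCSMLMTPVYPVGITGYNFDMFYANRLGPGLLAQKKIFNTYMWMWDGNICGY
DLTLFYWLVVCCHCPIKKAL
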