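>AP2_synth_01
ISPRQPENYEIIIEQDHVECYHTNLPMSIMWYKSKMECEHNTYACCSWAYQNQVYHPH
>AP2_synth_02
WSPRYPENYEIIIEQDHVECYHTNKPMSPQWYKSKMETEHNTYACCSWAIQNQVYSHP
>AP2_synth_03
SSPRYPENYEIIIEQDHVECYHTYLPMSPMWYKSKMHTEHNTYACCSWAIQNQVYSPH
>AP2_synth_04
WSPRYPENYEIMIEQDHVECCHTNLPMSPMWYKSKMHTEHNTYACCSWAIQNQVYSPH
>AP2_synth_05
WSPRYPENYMIIIEQDHVECYHTNLPMSPCWYKSKMETEHNTMACCSWAIQTQVYSPH
>AP2_synth_06
ISPRYIENYEIIIEQDHVECYHTKDPMSIMWYQSKMETEHNTYACCSWAIQNQVISPE
>AP2_synth_07
WSPRYPENYEIIIEQDHVRCYGTNLPMSPMWHKSKMETETNQWACFGWAIQNQVYSPH
>AP2_synth_08
WSPRYPENYEIIIEQDHVECYHTNLPMSPMWTKSKHETEHNIYACCSWAIQNQVYSPH
>AP2_synth_09
WSPHYPENYEIIIEQDHVECYHTNLPMSPWWYKSKMETEHNTYACCSWAQQNQVRSPH
>AP2_synth_10
WFPSYPENYEVIIEFDHVECYHTNLPMSPMWYKSRMETTHNTYACCSWAIQNQVYSPH
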