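>ERF_ref_1 subfamily=ERF
WSPRYPENYEIIIEQDHVECYHTNLPMSPMWYKSKMETEHNTYACCSWAIQNQVYSPH
>ERF_ref_2 subfamily=ERF
WSERYPENMEIIIEQDHVECYHTNLPMSPMWYKSKMETEHNTYACCSLAIQNQVYSPH
>DREB_ref_1 subfamily=DREB
GSPCHPENYEIIIEQLHVECYHTWLPMDPVWYSSSMETMHNTYACCSWAIQNQVYSPH
>DREB_ref_2 subfamily=DREB
GSECHPENMEIIIEQLHVECYHTWLPMDPVWYSSSMETMHNTYACCSLAIQNQVYSPH
>DRF_ref_1 subfamily=DRF
WSPRYPMNYEIRIEQDHVMCHQENTPMSPMWYKSKMEEEHWTYACCSWAIQWQVYSPH
>DRF_ref_2 subfamily=DRF
WSERYPMNMEIRIEQDHVMCHQENTPMSPMWYKSKMEEEHWTYACCSLAIQWQVYSPH
>SOLOIST_ref_1 subfamily=SOLOIST
WDPRYYENYEIIIMADQFECYHTNLYMSYMWYKDKMMTEQNEHAKKDWIRQNQVHDPH
>SOLOIST_ref_2 subfamily=SOLOIST
WDERYYENMEIIIMADQFECYHTNLYMSYMWYKDKMMTEQNEHAKKDLIRQNQVHDPH
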