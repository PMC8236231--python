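>AP2SEED1
PVYRGVRQRNSGKVAEIREPNEKCRIWLGTF--DTAETAARAVDRAAINLRGPSAE
>AP2SEED2
PVYRGVLQINSGKVAEGREPNKKSRIWLGTF--DTLEDAARGYDRAAIKLRGPSAR
>AP2SEED3
PVYRGVRQRNSRKVAEIREPNKKSRIWLGTF--DKREEAARATDRAAIKFRGPSAY
>AP2SEED4
PVYRGVRQRNSGKVAEIREPNKSSSLWLGTF--DTAEEAARAYDRAAIYLRGDSGR
>AP2SEED5
PVYRGVNQRNSGTVAEIREPCKKMRIWLGQF--DTAEEAARAYDRAAIKLRGLSAR
>AP2SEED6
PVYRGVFQINSGKVAEIREPNKKSRIWVGTF--DTAEEAIRARDRAAIKLRGPSQR
>AP2SEED7
PVDRGIRQRNSGKVAEAREPNKKARIWLGTF--CTAEEAARAYDRAAIKLRGPSAG
>AP2SEED8
PVYRGVRQRNSGMVVECREPFKKSRIWLGTFNGDTAEETAREYDRAAIKLRGPSAR
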