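# phrase	kind (pre_neg | post_neg | hedge)
kein	pre_neg
keine	pre_neg
keinen	pre_neg
keinem	pre_neg
keiner	pre_neg
ohne	pre_neg
nicht	pre_neg
Ausschluss	pre_neg
no	pre_neg
not	pre_neg
without	pre_neg
no signs of	pre_neg
no evidence of	pre_neg
ausgeschlossen	post_neg
Verdacht auf	hedge
möglich	hedge
möglicherweise	hedge
fraglich	hedge
suspected	hedge
possible	hedge
Prävention	hedge
Prophylaxe	hedge
Vorbeugung	hedge
Risiko	hedge
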