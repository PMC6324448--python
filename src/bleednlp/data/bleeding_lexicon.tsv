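kind	id_or_category	pattern	direction	examples
# Target stems. The first nine stems are named directly in the clinical
# bleeding term-frequency analysis (bleed, hemorr, hematoma, BRBPR, GIB,
# ICH, SAH, SDH, melena); the remaining seven are reconstructions from
# standard clinical bleeding vocabulary and are flagged [reconstructed].
target	bleed	\bbleed(?:ing|s|er)?\b|\bbled\b		bleeding;bleed;bled;bleeds
target	hemorr	\bha?emorrhag\w*		hemorrhage;hemorrhagic;hemorrhages;haemorrhage
target	hematoma	\bha?ematomas?\b		hematoma;hematomas;haematoma
target	brbpr	\bBRBPR\b		BRBPR
target	gib	\b[UL]?GIB\b		GIB;UGIB;LGIB
target	ich	\bICH\b		ICH
target	sah	\bSAH\b		SAH
target	sdh	\bSDH\b		SDH
target	melena	\bmelen(?:a|ic)\b		melena;melenic
# [reconstructed] stems below
target	ecchymos	\becchymo(?:sis|ses|tic)\b		ecchymosis;ecchymoses;ecchymotic
target	epistaxis	\bepistaxis\b		epistaxis
target	hematemesis	\bha?ematemesis\b		hematemesis;haematemesis
target	hematochezia	\bha?ematochezia\b		hematochezia
target	hemoptysis	\bha?emoptysis\b		hemoptysis;haemoptysis
target	hematuria	\bha?ematuria\b		hematuria;haematuria
target	coffee_ground	\bcoffee[- ]ground(?:s)?(?: emesis)?\b		coffee ground emesis;coffee-ground
# Context modifiers: any in-scope modifier flips a mention to bleeding-absent.
modifier	negation	\bden(?:ies|ied|ying|y)\b	forward	denies;denied
modifier	negation	\bno\b	forward	no
modifier	negation	\bnot\b	forward	not
modifier	negation	\bwithout\b	forward	without
modifier	negation	\bnegative for\b	forward	negative for
modifier	negation	\babsence of\b	forward	absence of
modifier	negation	\bfree of\b	forward	free of
modifier	negation	\bresolved\b	backward	resolved
modifier	negation	\bruled out\b	backward	ruled out
modifier	historical	\bhistory of\b|\bh/o\b|\bhx of\b	forward	history of;h/o;hx of
modifier	historical	\bprior\b|\bprevious\b|\bremote\b	forward	prior;previous;remote
modifier	historical	\bstatus post\b|\bs/p\b	forward	status post;s/p
modifier	hypothetical	\bif\b	forward	if
modifier	hypothetical	\bshould\b	forward	should
modifier	hypothetical	\brisk (?:of|for)\b	forward	risk of;risk for
modifier	hypothetical	\b(?:monitor|watch|return) for\b	forward	monitor for;watch for;return for
modifier	hypothetical	\bin case of\b|\bto prevent\b	forward	in case of;to prevent
modifier	hypothetical	\bprophylaxis\b	backward	prophylaxis
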