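# known non-medical word forms, shielded from spell correction
der	die	das	den	dem	des	ein	eine	einen	einem	einer
und	oder	mit	ohne	bei	nach	vor	unter	ueber	zur	zum
im	in	am	an	auf	fuer	von	aus	wir	sie	ist
sind	war	waren	wird	werden	wurde	wurden	sich	kein	keine	nicht
alter	jahre	jahr	geschlecht	weiblich	maennlich	neue	diagnosen	fruehere	medikation	befund
befunde	untersuchung	untersuchungen	ergaben	ergab	anhalt	hinweis	akute	erkrankungen	laborwerte	lagen
weitgehend	normbereich	insgesamt	altersentsprechende	danken	freundliche	teilnahme	studie	energy	x-ray	dual
absorptiometrie	absorptiometry	entlassungsbericht	empfehlen	empfohlen	koerperliche	aktivitaet	kontrolle	einnahme	bekannt	erhoehtem
praevention	prophylaxe	vorbeugung	verdacht	moeglich	fraglich	ausgeschlossen	ausschluss	tabletten	morgens	abends
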