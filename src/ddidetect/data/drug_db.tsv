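# trade_name	agent	concept_id
Antra	Omeprazol	P000001
Omep	Omeprazol	P000001
Pantozol	Pantoprazol	P000002
Rifun	Pantoprazol	P000002
Nexium	Esomeprazol	P000003
Esomep	Esomeprazol	P000003
Agopton	Lansoprazol	P000004
Lanzor	Lansoprazol	P000004
Dexilant	Dexlansoprazol	P000005
Kapidex	Dexlansoprazol	P000005
Pariet	Rabeprazol	P000006
Tenapra	Tenatoprazol	P000007
Ilapro	Ilaprazol	P000008
Timopra	Timoprazol	P000009
Picopra	Picoprazol	P000010
Leminopra	Leminoprazol	P000011
Anapra	Anaprazol	P000012
Disupra	Disuprazol	P000013
Aspirin	Acetylsalicylsäure	AG00001
Godamed	Acetylsalicylsäure	AG00001
Glucophage	Metformin	AG00002
Zocor	Simvastatin	AG00003
Euthyrox	Levothyroxin	AG00004
Berlthyrox	Levothyroxin	AG00004
Delix	Ramipril	AG00005
Vesdil	Ramipril	AG00005
Concor	Bisoprolol	AG00006
Vigantol	Colecalciferol	AG00007
Dekristol	Colecalciferol	AG00007
Calcimed	Calcium	AG00008
Nurofen	Ibuprofen	AG00009
Dolormin	Ibuprofen	AG00009
Esidrix	Hydrochlorothiazid	AG00010
Norvasc	Amlodipin	AG00011
Torem	Torasemid	AG00012
Unat	Torasemid	AG00012
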