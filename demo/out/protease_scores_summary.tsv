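combination	group	rule	score_mean	score_sd	n_rounds	n_nan
lys-c	large	1-unique	1.092201742544006	0.010839750526263733	5	0
lys-c	large	2-unique	1.0972123576019979	0.014442612251772798	5	0
lys-c	small	1-unique	1.2797990531533243	0.02705065231410093	5	0
lys-c	small	2-unique	1.2922531801822186	0.07625036600034771	5	0
lys-c+lysarginase	large	1-unique	1.4666094285818243	0.013917305344227216	5	0
lys-c+lysarginase	large	2-unique	1.4769086764283377	0.019519657594767748	5	0
lys-c+lysarginase	small	1-unique	1.5868925701862824	0.0443831758997081	5	0
lys-c+lysarginase	small	2-unique	1.6486432106332578	0.07296595583942016	5	0
lys-c+lysarginase+trypsin	large	1-unique	1.7335231720867221	0.01405889337539031	5	0
lys-c+lysarginase+trypsin	large	2-unique	1.7476626213693376	0.01796894115024959	5	0
lys-c+lysarginase+trypsin	small	1-unique	1.828084810581349	0.037064485809260694	5	0
lys-c+lysarginase+trypsin	small	2-unique	1.8940309762238379	0.06432890038852103	5	0
lys-c+trypsin	large	1-unique	1.4764642505195094	0.01406174737625461	5	0
lys-c+trypsin	large	2-unique	1.4873359242992825	0.01594010956787145	5	0
lys-c+trypsin	small	1-unique	1.6037763247915546	0.027003572479223293	5	0
lys-c+trypsin	small	2-unique	1.659694418693419	0.05750606304171772	5	0
lysarginase	large	1-unique	0.9698946515529856	0.005866715279786429	5	0
lysarginase	large	2-unique	0.9662156772628014	0.009487677424038188	5	0
lysarginase	small	1-unique	0.9708225343149411	0.054998116491021105	5	0
lysarginase	small	2-unique	0.9617414871389831	0.06326854673322813	5	0
lysarginase+trypsin	large	1-unique	1.3715437669866	0.009775805875431443	5	0
lysarginase+trypsin	large	2-unique	1.3721983044861206	0.009451740197682829	5	0
lysarginase+trypsin	small	1-unique	1.3739551416778324	0.03211183146510918	5	0
lysarginase+trypsin	small	2-unique	1.3716608332370903	0.04027282692029418	5	0
trypsin	large	1-unique	1.0	0.0	5	0
trypsin	large	2-unique	1.0	0.0	5	0
trypsin	small	1-unique	1.0	0.0	5	0
trypsin	small	2-unique	1.0	0.0	5	0
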