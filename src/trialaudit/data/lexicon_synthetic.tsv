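# Synthetic stand-in lexicon for exact-match coverage analysis.
# Columns: source_id <TAB> preferred_name <TAB> identifier
# A small hand-authored table of term -> vocabulary-identifier rows shaped
# like an exported MeSH/MedDRA/SNOMED-CT preferred-name space. Identifiers
# are synthetic and carry no meaning outside this package.
MESH	type 2 diabetes mellitus	MESH:D003924
MESH	hypertension	MESH:D006973
MESH	asthma	MESH:D001249
MESH	breast cancer	MESH:D001943
MESH	chronic obstructive pulmonary disease	MESH:D029424
MESH	major depressive disorder	MESH:D003865
MESH	rheumatoid arthritis	MESH:D001172
MESH	atrial fibrillation	MESH:D001281
MESH	alzheimer disease	MESH:D000544
MESH	obesity	MESH:D009765
MESH	migraine	MESH:D008881
MESH	psoriasis	MESH:D011565
MESH	chronic kidney disease	MESH:D051436
MESH	heart failure	MESH:D006333
MESH	osteoarthritis	MESH:D010003
MESH	epilepsy	MESH:D004827
MESH	parkinson disease	MESH:D010300
MESH	stroke	MESH:D020521
MESH	anemia	MESH:D000740
MESH	melanoma	MESH:D008545
MEDDRA	type 2 diabetes mellitus	MEDDRA:10067585
MEDDRA	hypertension	MEDDRA:10020772
MEDDRA	asthma	MEDDRA:10003553
MEDDRA	breast cancer	MEDDRA:10006187
MEDDRA	atrial fibrillation	MEDDRA:10003658
MEDDRA	migraine	MEDDRA:10027599
MEDDRA	psoriasis	MEDDRA:10037153
MEDDRA	heart failure	MEDDRA:10019279
MEDDRA	anemia	MEDDRA:10002034
MEDDRA	melanoma	MEDDRA:10053571
SNOMEDCT	type 2 diabetes mellitus	SNOMEDCT:44054006
SNOMEDCT	hypertension	SNOMEDCT:38341003
SNOMEDCT	asthma	SNOMEDCT:195967001
SNOMEDCT	chronic obstructive pulmonary disease	SNOMEDCT:13645005
SNOMEDCT	rheumatoid arthritis	SNOMEDCT:69896004
SNOMEDCT	obesity	SNOMEDCT:414916001
SNOMEDCT	chronic kidney disease	SNOMEDCT:709044004
SNOMEDCT	heart failure	SNOMEDCT:84114007
SNOMEDCT	epilepsy	SNOMEDCT:84757009
SNOMEDCT	stroke	SNOMEDCT:230690007
RXNORM	metformin	RXNORM:6809
RXNORM	atorvastatin	RXNORM:83367
RXNORM	lisinopril	RXNORM:29046
MESH	metformin	MESH:D008687
MESH	atorvastatin	MESH:D000069059
MESH	insulin pump	MESH:D007332
MESH	cardiac pacemaker	MESH:D010138
SNOMEDCT	continuous glucose monitor	SNOMEDCT:467566006
MESH	influenza vaccine	MESH:D007252
RXNORM	rituximab	RXNORM:121191
RXNORM	adalimumab	RXNORM:327361
SNOMEDCT	coronary artery bypass grafting	SNOMEDCT:232717009
SNOMEDCT	total knee arthroplasty	SNOMEDCT:609588000
SNOMEDCT	laparoscopic cholecystectomy	SNOMEDCT:45595009
MESH	stereotactic body radiotherapy	MESH:D066124
MESH	proton beam therapy	MESH:D061766
MESH	brachytherapy	MESH:D001918
MESH	cognitive behavioral therapy	MESH:D015928
SNOMEDCT	motivational interviewing	SNOMEDCT:445172007
MESH	mindfulness-based stress reduction	MESH:D064866
MESH	gene transfer therapy	MESH:D015316
MESH	antisense oligonucleotide	MESH:D016376
MESH	car t-cell therapy	MESH:D000076962
MESH	vitamin d	MESH:D014807
MESH	omega-3 fatty acids	MESH:D015525
MESH	probiotics	MESH:D019936
SNOMEDCT	drug-eluting stent	SNOMEDCT:426390005
SNOMEDCT	antibiotic-loaded bone cement	SNOMEDCT:425222002
MEDDRA	naloxone auto-injector	MEDDRA:10079999
MESH	magnetic resonance imaging	MESH:D008279
MESH	polymerase chain reaction test	MESH:D016133
SNOMEDCT	colonoscopy	SNOMEDCT:73761001
MESH	placebo	MESH:D010919
SNOMEDCT	standard of care	SNOMEDCT:394841004
MESH	exercise program	MESH:D005081
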