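# pool<TAB>surface
indication	breast cancer
indication	ovarian cancer
indication	lung cancer
indication	colorectal cancer
indication	prostate cancer
indication	gastric cancer
indication	pancreatic carcinoma
indication	bladder carcinoma
indication	renal cell carcinoma
indication	multiple myeloma
indication	non small cell carcinoma
indication	hodgkin lymphoma
indication	non hodgkin lymphoma
indication	acute leukemia
indication	chronic leukemia
indication	rheumatoid arthritis
indication	psoriatic arthritis
indication	ankylosing spondylitis
indication	systemic lupus
indication	crohn disease
indication	ulcerative proctitis
indication	diabetes mellitus
indication	chronic heart failure
indication	ischemic stroke prevention
indication	coronary artery disease
indication	chronic obstructive airway disease
indication	asthma exacerbation prophylaxis
indication	peptic ulcer disease
indication	gastroesophageal reflux
indication	epilepsy
indication	bipolar disorder
indication	major depressive disorder
indication	schizoaffective disorder
indication	osteoarthritis
indication	gout prophylaxis
indication	hyperlipidemia
indication	essential thrombocythemia
indication	endometrial carcinoma
indication	head and neck carcinoma
indication	melanoma
indication	glioblastoma
indication	soft tissue sarcoma
indication	esophageal carcinoma
indication	hepatocellular carcinoma
indication	cholangiocarcinoma
indication	cervical carcinoma
indication	testicular carcinoma
indication	thyroid carcinoma
indication	mesothelioma
indication	neuroblastoma
ossd	weight loss
ossd	weight gain
ossd	night sweats
ossd	loss of appetite
ossd	abdominal distension
ossd	abdominal discomfort
ossd	back pain
ossd	chest tightness
ossd	chest discomfort
ossd	blurred vision
ossd	dry mouth
ossd	sore throat
ossd	runny nose
ossd	nasal congestion
ossd	muscle cramps
ossd	joint stiffness
ossd	neck stiffness
ossd	generalized weakness
ossd	poor oral intake
ossd	reduced exercise tolerance
ossd	swollen ankles
ossd	cold extremities
ossd	pale appearance
ossd	irregular pulse
ossd	rapid breathing
ossd	shallow breathing
ossd	productive sputum
ossd	clammy skin
ossd	mottled skin
ossd	skin discoloration
ossd	brittle nails
ossd	hair thinning
ossd	mouth dryness
ossd	excessive thirst
ossd	frequent urination
ossd	nocturnal awakening
ossd	restless legs
ossd	low grade pyrexia
ossd	elevated troponin level
ossd	increased creatinine level
ossd	low platelet count
ossd	borderline glucose level
ossd	abnormal liver panel
ossd	prolonged bleeding time
ossd	irregular menses
ossd	postural unsteadiness
ossd	slowed speech
ossd	flattened affect
ossd	poor concentration
ossd	memory lapses
treatment	blood transfusion
treatment	platelet transfusion
treatment	red packed cells
treatment	plasma exchange
treatment	hemodialysis
treatment	peritoneal dialysis
treatment	mechanical ventilation
treatment	supplemental oxygen therapy
treatment	intravenous fluids
treatment	fluid resuscitation
treatment	vasopressor support
treatment	cardiac catheterization
treatment	coronary angioplasty
treatment	stent placement
treatment	pacemaker implantation
treatment	cardioversion
treatment	defibrillation
treatment	endoscopic hemostasis
treatment	surgical debridement
treatment	wound drainage
treatment	splenectomy
treatment	appendectomy
treatment	cholecystectomy
treatment	mastectomy
treatment	lumpectomy
treatment	hysterectomy
treatment	tumor resection
treatment	radiation therapy
treatment	radiotherapy
treatment	chemotherapy discontinuation
treatment	dose reduction
treatment	drug withdrawal
treatment	supportive care
treatment	physical therapy
treatment	occupational therapy
treatment	speech therapy
treatment	bowel rest
treatment	nasogastric decompression
treatment	chest physiotherapy
treatment	bronchoscopy
treatment	thoracentesis
treatment	paracentesis
treatment	lumbar puncture
treatment	skin grafting
treatment	debulking surgery
treatment	exploratory laparotomy
treatment	re-exposure
treatment	rechallenge
route	intravenous
route	intravenously
route	oral
route	orally
route	subcutaneous
route	subcutaneously
route	intramuscular
route	intramuscularly
route	topical
route	topically
route	inhaled
route	by inhalation
route	by mouth
route	by infusion
route	via infusion
route	intrathecal
route	intrathecally
route	transdermal
route	rectal
route	sublingual
route	by injection
route	via central line
route	via peripheral line
route	intraperitoneal
route	nebulized
route	by nasogastric tube
route	intraarterial
route	ocular
route	intradermal
route	by drip
frequency	once daily
frequency	twice daily
frequency	three times daily
frequency	four times daily
frequency	every morning
frequency	every evening
frequency	every other day
frequency	once weekly
frequency	twice weekly
frequency	every three weeks
frequency	every four weeks
frequency	as needed
frequency	at bedtime
frequency	every six hours
frequency	every eight hours
frequency	every twelve hours
frequency	once monthly
frequency	with meals
frequency	before meals
frequency	after meals
duration	three hour
duration	two week
duration	five day
duration	ten day
duration	six month
duration	three week
duration	two day
duration	four day
duration	one week
duration	two month
duration	seven day
duration	fourteen day
duration	twenty eight day
duration	forty eight hour
duration	twelve hour
duration	one month
duration	six week
duration	three day
duration	nine week
duration	one year
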