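split	target	positives
train	adrb1	247
train	adrb2	231
train	akt2	117
train	ampc	48
train	andr	269
train	aofb	122
train	bace1	283
train	braf	152
train	cah2	492
train	cdk2	474
train	cp2c9	120
train	csf1r	166
train	cxcr4	40
train	def	102
train	dhi1	330
train	drd3	480
train	dyr	231
train	esr1	383
train	esr2	367
train	fa7	114
train	fabp4	47
train	fak1	100
train	fkb1a	111
train	fpps	85
train	gcr	258
train	glcm	54
train	hdac2	185
train	hivint	100
train	hivpr	536
train	hivrt	338
train	hmdh	170
train	hs90a	88
train	hxk4	92
train	igf1r	148
train	inha	43
train	ital	138
train	jak2	107
train	kif11	116
train	lck	420
train	mapk2	101
train	mcr	94
train	mk01	79
train	mk10	104
train	mk14	578
train	mmp13	572
train	nos1	100
train	nram	98
train	pde5a	398
train	pgh2	435
train	plk1	107
train	pnph	103
train	ppara	373
train	ppard	240
train	pparg	484
train	prgr	293
train	pur2	50
train	reni	104
train	rock1	100
train	rxra	131
train	sahh	63
train	src	524
train	thb	103
train	try1	449
train	tryb1	148
train	tysy	109
train	urok	162
train	vgfr2	409
train	xiap	100
test	aa2ar	482
test	abl1	182
test	aces	453
test	ada	93
test	casp3	199
test	cp3a4	170
test	egfr	542
test	fa10	537
test	fgfr1	139
test	fnta	592
test	grik1	101
test	hdac8	170
test	kit	166
test	kith	57
test	kpcb	135
test	pa2ga	99
test	parp1	508
test	pgh1	195
test	ptn1	130
test	pygm	77
test	pyrd	111
test	tgfr1	133
test	wee1	102
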