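caresses	caress
ponies	poni
ties	ti
caress	caress
cats	cat
feed	feed
agreed	agre
plastered	plaster
bled	bled
motoring	motor
sing	sing
conflated	conflat
troubled	troubl
sized	size
hopping	hop
tanned	tan
falling	fall
hissing	hiss
fizzed	fizz
failing	fail
filing	file
happy	happi
sky	sky
relational	relat
conditional	condit
rational	ration
valenci	valenc
hesitanci	hesit
digitizer	digit
conformabli	conform
radicalli	radic
differentli	differ
vileli	vile
analogousli	analog
vietnamization	vietnam
predication	predic
operator	oper
feudalism	feudal
decisiveness	decis
hopefulness	hope
callousness	callous
formaliti	formal
sensitiviti	sensit
sensibiliti	sensibl
triplicate	triplic
formative	form
formalize	formal
electriciti	electr
electrical	electr
hopeful	hope
goodness	good
revival	reviv
allowance	allow
inference	infer
airliner	airlin
gyroscopic	gyroscop
adjustable	adjust
defensible	defens
irritant	irrit
replacement	replac
adjustment	adjust
dependent	depend
adoption	adopt
homologou	homolog
communism	commun
activate	activ
angulariti	angular
effective	effect
bowdlerize	bowdler
probate	probat
rate	rate
cease	ceas
controll	control
roll	roll
studies	studi
studying	studi
study	studi
crying	cry
cried	cri
flies	fli
dying	dy
lying	ly
tying	ty
stemming	stem
stemmed	stem
argument	argument
arguments	argument
argued	argu
arguing	argu
prevalence	preval
prevalent	preval
violence	violenc
violent	violent
victims	victim
victimization	victim
abusive	abus
screening	screen
screened	screen
relevant	relev
workers	worker
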