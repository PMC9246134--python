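was	be
were	be
is	be
are	be
am	be
been	be
being	be
has	have
had	have
having	have
does	do
did	do
done	do
doing	do
went	go
gone	go
goes	go
going	go
said	say
says	say
saying	say
made	make
makes	make
making	make
took	take
taken	take
takes	take
taking	take
gave	give
given	give
gives	give
giving	give
found	find
finds	find
finding	find
showed	show
shown	show
shows	show
showing	show
men	man
women	woman
children	child
people	person
feet	foot
teeth	tooth
mice	mouse
lives	life
wives	wife
knives	knife
leaves	leaf
selves	self
halves	half
analyses	analysis
diagnoses	diagnosis
hypotheses	hypothesis
theses	thesis
crises	crisis
criteria	criterion
phenomena	phenomenon
data	datum
media	medium
bacteria	bacterium
indices	index
matrices	matrix
appendices	appendix
better	good
best	good
worse	bad
worst	bad
less	little
least	little
more	many
most	many
further	far
furthest	far
ran	run
running	run
runs	run
began	begin
begun	begin
begins	begin
beginning	begin
became	become
becomes	become
becoming	become
brought	bring
brings	bring
bringing	bring
bought	buy
buys	buy
buying	buy
came	come
comes	come
coming	come
chose	choose
chosen	choose
chooses	choose
choosing	choose
drew	draw
drawn	draw
draws	draw
drawing	draw
fell	fall
fallen	fall
falls	fall
falling	fall
felt	feel
feels	feel
feeling	feel
got	get
gotten	get
gets	get
getting	get
grew	grow
grown	grow
grows	grow
growing	grow
held	hold
holds	hold
holding	hold
kept	keep
keeps	keep
keeping	keep
knew	know
known	know
knows	know
knowing	know
led	lead
leads	lead
leading	lead
left	leave
leaving	leave
lost	lose
loses	lose
losing	lose
met	meet
meets	meet
meeting	meet
paid	pay
pays	pay
paying	pay
put	put
puts	put
putting	put
read	read
reads	read
reading	read
reported	report
reports	report
reporting	report
rose	rise
risen	rise
rises	rise
rising	rise
saw	see
seen	see
sees	see
seeing	see
sought	seek
seeks	seek
seeking	seek
sold	sell
sells	sell
selling	sell
sent	send
sends	send
sending	send
spoke	speak
spoken	speak
speaks	speak
speaking	speak
spent	spend
spends	spend
spending	spend
stood	stand
stands	stand
standing	stand
taught	teach
teaches	teach
teaching	teach
told	tell
tells	tell
telling	tell
thought	think
thinks	think
thinking	think
understood	understand
understands	understand
understanding	understand
wrote	write
written	write
writes	write
writing	write
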