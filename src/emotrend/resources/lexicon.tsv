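# word <TAB> emotion; emotion in {anger, fear, happiness, sadness, surprise}.
# Each word maps to exactly one emotion; all entries lowercase alphabetic.
# Compiled for this package from common English emotion-word associations
# (openly licensed); not a copy of any third-party tool's dictionary.
angry	anger
anger	anger
furious	anger
fury	anger
rage	anger
raging	anger
enraged	anger
irritated	anger
irritating	anger
annoyed	anger
annoying	anger
mad	anger
outraged	anger
outrage	anger
resent	anger
resentful	anger
hostile	anger
hostility	anger
hate	anger
hated	anger
hates	anger
hating	anger
hatred	anger
bitter	anger
frustrated	anger
frustrating	anger
frustration	anger
aggravated	anger
infuriating	anger
infuriated	anger
livid	anger
seething	anger
pissed	anger
grudge	anger
vengeful	anger
spite	anger
spiteful	anger
wrath	anger
irate	anger
fuming	anger
disgusted	anger
disgust	anger
disgusting	anger
scorn	anger
contempt	anger
insulted	anger
offended	anger
betrayed	anger
jealous	anger
jealousy	anger
envious	anger
fear	fear
fearful	fear
afraid	fear
scared	fear
scare	fear
scares	fear
scary	fear
terrified	fear
terrifying	fear
terror	fear
horror	fear
horrified	fear
horrifying	fear
dread	fear
dreading	fear
dreadful	fear
panic	fear
panicked	fear
panicking	fear
anxious	fear
anxiety	fear
worried	fear
worry	fear
worries	fear
worrying	fear
nervous	fear
nervousness	fear
frightened	fear
frightening	fear
fright	fear
alarmed	fear
alarming	fear
threat	fear
threatened	fear
threatening	fear
uneasy	fear
unease	fear
apprehensive	fear
phobia	fear
paranoid	fear
paranoia	fear
timid	fear
shaken	fear
petrified	fear
insecure	fear
danger	fear
dangerous	fear
overwhelmed	fear
happy	happiness
happiness	happiness
joy	happiness
joyful	happiness
joyous	happiness
glad	happiness
delighted	happiness
delight	happiness
delightful	happiness
cheerful	happiness
cheer	happiness
cheery	happiness
pleased	happiness
pleasant	happiness
pleasure	happiness
smile	happiness
smiling	happiness
smiles	happiness
laugh	happiness
laughing	happiness
laughter	happiness
love	happiness
loved	happiness
loves	happiness
loving	happiness
lovely	happiness
wonderful	happiness
awesome	happiness
fantastic	happiness
excellent	happiness
excited	happiness
exciting	happiness
excitement	happiness
thrilled	happiness
grateful	happiness
gratitude	happiness
thankful	happiness
thanks	happiness
blessed	happiness
bliss	happiness
blissful	happiness
satisfied	happiness
satisfying	happiness
fun	happiness
funny	happiness
enjoy	happiness
enjoyed	happiness
enjoying	happiness
enjoyable	happiness
hopeful	happiness
optimistic	happiness
proud	happiness
celebrate	happiness
celebration	happiness
glee	happiness
elated	happiness
sad	sadness
sadness	sadness
unhappy	sadness
sorrow	sadness
sorrowful	sadness
grief	sadness
grieving	sadness
mourn	sadness
mourning	sadness
miserable	sadness
misery	sadness
depressed	sadness
depressing	sadness
depression	sadness
gloomy	sadness
gloom	sadness
heartbroken	sadness
heartbreak	sadness
crying	sadness
cried	sadness
cry	sadness
cries	sadness
tears	sadness
tearful	sadness
weep	sadness
weeping	sadness
lonely	sadness
loneliness	sadness
hopeless	sadness
hopelessness	sadness
despair	sadness
desperate	sadness
desperation	sadness
hurt	sadness
hurting	sadness
pain	sadness
painful	sadness
ashamed	sadness
shame	sadness
guilt	sadness
guilty	sadness
regret	sadness
regretful	sadness
disappointed	sadness
disappointing	sadness
disappointment	sadness
suicidal	sadness
suicide	sadness
worthless	sadness
grim	sadness
somber	sadness
melancholy	sadness
anguish	sadness
agony	sadness
devastated	sadness
devastating	sadness
surprise	surprise
surprised	surprise
surprising	surprise
surprises	surprise
astonished	surprise
astonishing	surprise
astonishment	surprise
amazed	surprise
amazement	surprise
amazing	surprise
astounded	surprise
astounding	surprise
stunned	surprise
stunning	surprise
shocked	surprise
shocking	surprise
shock	surprise
unexpected	surprise
unexpectedly	surprise
sudden	surprise
suddenly	surprise
startling	surprise
startled	surprise
unbelievable	surprise
incredible	surprise
incredibly	surprise
wow	surprise
whoa	surprise
woah	surprise
bewildered	surprise
bewildering	surprise
baffled	surprise
baffling	surprise
dumbfounded	surprise
flabbergasted	surprise
speechless	surprise
marvel	surprise
miracle	surprise
miraculous	surprise
gasp	surprise
gasped	surprise
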