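# Neutral vocabulary for the synthetic text generator: common, concrete,
# non-emotion words. None of these appear in lexicon.tsv, stopwords.txt, or
# as a key in contractions.tsv (a test enforces this).
school
class
teacher
homework
game
games
gaming
music
song
video
phone
computer
internet
week
weekend
today
tomorrow
morning
night
dinner
lunch
food
pizza
friend
friends
family
brother
sister
parents
house
room
city
town
street
weather
rain
snow
summer
winter
book
books
reading
writing
movie
movies
show
series
episode
sports
soccer
basketball
running
walking
bike
car
bus
train
store
shopping
money
job
work
working
project
test
exam
grade
question
answer
idea
plan
time
year
month
people
person
world
country
news
post
comment
thread
online
account
picture
photo
camera
dog
cat
pet
coffee
tea
water
sleep
breakfast
chair
table
window
door
garden
tree
park
beach
mountain
river
keyboard
screen
headphones
guitar
piano
drawing
painting
science
math
history
language
practice
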