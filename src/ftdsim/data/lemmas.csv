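form,lemma
going,go
goes,go
went,go
gone,go
running,run
runs,run
ran,run
dogs,dog
cats,cat
children,child
men,man
women,woman
people,person
feet,foot
teeth,tooth
mice,mouse
geese,goose
leaves,leaf
lives,life
wives,wife
knives,knife
days,day
ways,way
things,thing
times,time
years,year
words,word
sentences,sentence
stories,story
houses,house
cars,car
books,book
ideas,idea
thoughts,thought
friends,friend
families,family
parents,parent
brothers,brother
sisters,sister
doctors,doctor
teachers,teacher
students,student
cities,city
countries,country
places,place
rooms,room
doors,door
windows,window
tables,table
chairs,chair
walls,wall
streets,street
roads,road
trees,tree
flowers,flower
birds,bird
fishes,fish
horses,horse
animals,animal
eyes,eye
hands,hand
arms,arm
legs,leg
heads,head
faces,face
voices,voice
minds,mind
bodies,body
hearts,heart
took,take
taking,take
takes,take
taken,take
making,make
makes,make
made,make
saying,say
says,say
said,say
getting,get
gets,get
got,get
gotten,get
seeing,see
sees,see
saw,see
seen,see
knowing,know
knows,know
knew,know
known,know
thinking,think
thinks,think
thought,think
coming,come
comes,come
came,come
wanting,want
wants,want
wanted,want
using,use
uses,use
used,use
finding,find
finds,find
found,find
giving,give
gives,give
gave,give
given,give
telling,tell
tells,tell
told,tell
working,work
works,work
worked,work
calling,call
calls,call
called,call
trying,try
tries,try
tried,try
asking,ask
asks,ask
asked,ask
needing,need
needs,need
needed,need
feeling,feel
feels,feel
felt,feel
becoming,become
becomes,become
became,become
leaving,leave
leaves,leave
left,leave
putting,put
puts,put
meaning,mean
means,mean
meant,mean
keeping,keep
keeps,keep
kept,keep
letting,let
lets,let
beginning,begin
begins,begin
began,begin
begun,begin
playing,play
plays,play
played,play
moving,move
moves,move
moved,move
living,live
lived,live
believing,believe
believes,believe
believed,believe
bringing,bring
brings,bring
brought,bring
happening,happen
happens,happen
happened,happen
writing,write
writes,write
wrote,write
written,write
sitting,sit
sits,sit
sat,sit
standing,stand
stands,stand
stood,stand
losing,lose
loses,lose
lost,lose
paying,pay
pays,pay
paid,pay
meeting,meet
meets,meet
met,meet
talking,talk
talks,talk
talked,talk
turning,turn
turns,turn
turned,turn
starting,start
starts,start
started,start
showing,show
shows,show
showed,show
shown,show
hearing,hear
hears,hear
heard,hear
holding,hold
holds,hold
held,hold
walking,walk
walks,walk
walked,walk
sleeping,sleep
sleeps,sleep
slept,sleep
eating,eat
eats,eat
ate,eat
eaten,eat
drinking,drink
drinks,drink
drank,drink
reading,read
reads,read
looking,look
looks,look
looked,look
helping,help
helps,help
helped,help
opening,open
opens,open
opened,open
closing,close
closes,close
closed,close
buying,buy
buys,buy
bought,buy
bigger,big
biggest,big
smaller,small
smallest,small
better,good
best,good
worse,bad
worst,bad
older,old
oldest,old
younger,young
youngest,young
happier,happy
happiest,happy
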