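label,synonyms,met_value,category
sleep,sleeping|nap|napping,0.9,sleep
rest,resting|relax|relaxing|lying down,1.3,sedentary
sit,sitting,1.3,sedentary
tv,television|watching tv,1.3,sedentary
read,reading,1.3,sedentary
study,studying|homework,1.8,sedentary
class,lecture,1.8,sedentary
work,desk work|office work,1.5,occupation
computer,pc|typing,1.3,sedentary
meeting,,1.5,occupation
meal,eating|breakfast|lunch|dinner|snack,1.5,domestic
cooking,cook|preparing food,2.0,domestic
dishes,washing dishes,1.8,domestic
cleaning,tidying|housework|sweeping,2.5,domestic
vacuuming,vacuum,3.3,domestic
laundry,washing clothes,2.0,domestic
shopping,grocery shopping,2.3,domestic
bathing,bath|shower|showering,1.5,self-care
grooming,dressing|washing up,2.0,self-care
piano,music practice,2.3,leisure
walking,walk|stroll|strolling,3.5,locomotion
dog walking,walking the dog,3.0,locomotion
stairs,climbing stairs,4.0,locomotion
bicycling,cycling|bike|biking|bicycle,6.8,locomotion
driving,drive,2.5,locomotion
bus,train|commuting by bus,1.3,locomotion
running,run|jog|jogging,7.0,sports
training,workout|gym|gym training,5.0,sports
weightlifting,weights|strength training,3.5,sports
stretching,stretch,2.3,sports
yoga,,2.5,sports
calisthenics,exercises,3.8,sports
gardening,yard work,3.8,domestic
soccer,football,7.0,sports
basketball,,6.5,sports
tennis,,7.3,sports
badminton,,5.5,sports
volleyball,,4.0,sports
baseball,catch,5.0,sports
swimming,swim,6.0,sports
dancing,dance,4.8,sports
hiking,hike,6.0,sports
golf,,4.8,sports
table tennis,ping pong,4.0,sports
skiing,ski,7.0,sports
skating,skate,7.0,sports
martial arts,judo|karate,10.3,sports
boxing,sparring,7.8,sports
climbing,rock climbing,8.0,sports
sports,sport|game,6.0,sports
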