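;;; avsin mini-lexicon (CMU pronouncing-dictionary text format)
;;; Hand-authored fixture: ~190 common American-English words with ARPAbet
;;; pronunciations including lexical stress digits. Covers all 39 phonemes.
;;; Format: WORD  PH1 PH2 ...   with "(n)" suffixes for alternate variants.
A  AH0
A(2)  EY1
ALTHOUGH  AO0 L DH OW1
AND  AE1 N D
AUGUST  AO1 G AH0 S T
BABY  B EY1 B IY0
BASKET  B AE1 S K AH0 T
BATCH  B AE1 CH
BATH  B AE1 TH
BED  B EH1 D
BIRD  B ER1 D
BLUE  B L UW1
BOAT  B OW1 T
BOOK  B UH1 K
BOOT  B UW1 T
BOOTH  B UW1 TH
BOTTLE  B AA1 T AH0 L
BOY  B OY1
BREAD  B R EH1 D
BREATHE  B R IY1 DH
BROTHER  B R AH1 DH ER0
BROWN  B R AW1 N
BUTTER  B AH1 T ER0
CAKE  K EY1 K
CANDLE  K AE1 N D AH0 L
CAR  K AA1 R
CASTLE  K AE1 S AH0 L
CAT  K AE1 T
CHICKEN  CH IH1 K AH0 N
CHIEF  CH IY1 F
CHURCH  CH ER1 CH
CLOUD  K L AW1 D
COFFEE  K AA1 F IY0
COIN  K OY1 N
COTTON  K AA1 T AH0 N
COULD  K UH1 D
CROWD  K R AW1 D
CUP  K AH1 P
DARK  D AA1 R K
DAUGHTER  D AO1 T ER0
DAY  D EY1
DINNER  D IH1 N ER0
DOCTOR  D AA1 K T ER0
DOG  D AO1 G
DRAGON  D R AE1 G AH0 N
DREAM  D R IY1 M
ECHO  EH1 K OW0
ECHOES  EH1 K OW0 Z
ECHOS  EH1 K OW0 Z
EITHER  IY1 DH ER0
EITHER(2)  AY1 DH ER0
ESSAY  EH1 S EY2
ETHIC  EH1 TH IH0 K
FACE  F EY1 S
FARM  F AA1 R M
FATHER  F AA1 DH ER0
FEATHER  F EH1 DH ER0
FINGER  F IH1 NG G ER0
FIRST  F ER1 S T
FISH  F IH1 SH
FIVE  F AY1 V
FLOWER  F L AW1 ER0
FOOT  F UH1 T
FOREST  F AO1 R AH0 S T
FRIEND  F R EH1 N D
FULL  F UH1 L
GARAGE  G ER0 AA1 ZH
GARDEN  G AA1 R D AH0 N
GIANT  JH AY1 AH0 N T
GIRL  G ER1 L
GLASS  G L AE1 S
GLOVE  G L AH1 V
GO  G OW1
GOLDEN  G OW1 L D AH0 N
GOOD  G UH1 D
GRASS  G R AE1 S
GREEN  G R IY1 N
GUITAR  G IH0 T AA1 R
HAMMER  HH AE1 M ER0
HAND  HH AE1 N D
HAPPY  HH AE1 P IY0
HEART  HH AA1 R T
HEAVY  HH EH1 V IY0
HOLE  HH OW1 L
HONEY  HH AH1 N IY0
HOUSE  HH AW1 S
IN  IH1 N
IS  IH1 Z
ISLAND  AY1 L AH0 N D
IT  IH1 T
JUDGE  JH AH1 JH
JUNGLE  JH AH1 NG G AH0 L
KING  K IH1 NG
KITCHEN  K IH1 CH AH0 N
KNIFE  N AY1 F
LADDER  L AE1 D ER0
LADY  L EY1 D IY0
LAW  L AO1
LAWYER  L AO1 Y ER0
LEAF  L IY1 F
LEATHER  L EH1 DH ER0
LEMON  L EH1 M AH0 N
LETTER  L EH1 T ER0
LIFE  L AY1 F
LIVE  L IH1 V
LIVE(2)  L AY1 V
LOATHE  L OW1 DH
LOVE  L AH1 V
MACHINE  M AH0 SH IY1 N
MAGIC  M AE1 JH IH0 K
MAP  M AE1 P
MARKET  M AA1 R K AH0 T
MEASURE  M EH1 ZH ER0
MEMBER  M EH1 M B ER0
MOON  M UW1 N
MORNING  M AO1 R N IH0 NG
MOTHER  M AH1 DH ER0
MOUNTAIN  M AW1 N T AH0 N
MOUTH  M AW1 TH
MOVIE  M UW1 V IY0
MUD  M AH1 D
MUSIC  M Y UW1 Z IH0 K
NEVER  N EH1 V ER0
NIGHT  N AY1 T
NO  N OW1
NORTH  N AO1 R TH
NOTHING  N AH1 TH IH0 NG
NUMBER  N AH1 M B ER0
NURSE  N ER1 S
OCEAN  OW1 SH AH0 N
OF  AH1 V
OIL  OY1 L
ON  AA1 N
ONION  AH1 N Y AH0 N
PAPER  P EY1 P ER0
PENCIL  P EH1 N S AH0 L
PEOPLE  P IY1 P AH0 L
PHONE  F OW1 N
PICTURE  P IH1 K CH ER0
PLANET  P L AE1 N AH0 T
PLEASURE  P L EH1 ZH ER0
POISON  P OY1 Z AH0 N
POLICY  P AA1 L AH0 S IY0
POLISH  P AA1 L IH0 SH
POWDER  P AW1 D ER0
PURPLE  P ER1 P AH0 L
PUSH  P UH1 SH
QUEEN  K W IY1 N
RABBIT  R AE1 B AH0 T
RAIN  R EY1 N
READ  R IY1 D
READ(2)  R EH1 D
RED  R EH1 D
RING  R IH1 NG
RIVER  R IH1 V ER0
ROAD  R OW1 D
ROCKET  R AA1 K AH0 T
ROYAL  R OY1 AH0 L
SAFE  S EY1 F
SAW  S AO1
SCHOOL  S K UW1 L
SEA  S IY1
SEASON  S IY1 Z AH0 N
SECOND  S EH1 K AH0 N D
SEE  S IY1
SEVEN  S EH1 V AH0 N
SHADOW  SH AE1 D OW0
SHOE  SH UW1
SHOULDER  SH OW1 L D ER0
SILVER  S IH1 L V ER0
SISTER  S IH1 S T ER0
SKY  S K AY1
SMALL  S M AO1 L
SMOOTH  S M UW1 DH
SNAKE  S N EY1 K
SNOW  S N OW1
SONG  S AO1 NG
SOUTH  S AW1 TH
SPIDER  S P AY1 D ER0
SPOON  S P UW1 N
SPOUT  S P AW1 T
SPRING  S P R IH1 NG
STAR  S T AA1 R
STONE  S T OW1 N
STOVE  S T OW1 V
SUGAR  SH UH1 G ER0
SUMMER  S AH1 M ER0
SUN  S AH1 N
TABLE  T EY1 B AH0 L
TALK  T AO1 K
TEACHER  T IY1 CH ER0
TEETH  T IY1 TH
THANK  TH AE1 NG K
THE  DH AH0
THE(2)  DH IY0
THICK  TH IH1 K
THIN  TH IH1 N
THINK  TH IH1 NG K
THIRD  TH ER1 D
THIRTY  TH ER1 T IY0
THIS  DH IH1 S
THUNDER  TH AH1 N D ER0
TIGER  T AY1 G ER0
TIME  T AY1 M
TO  T UW1
TOOTH  T UW1 TH
TOWER  T AW1 ER0
TOY  T OY1
TRAIN  T R EY1 N
TRAVEL  T R AE1 V AH0 L
TREASURE  T R EH1 ZH ER0
TREE  T R IY1
USE  Y UW1 S
USE(2)  Y UW1 Z
VALLEY  V AE1 L IY0
VILLAGE  V IH1 L IH0 JH
VISION  V IH1 ZH AH0 N
VOICE  V OY1 S
VOTE  V OW1 T
WAGON  W AE1 G AH0 N
WAR  W AO1 R
WATER  W AO1 T ER0
WAVE  W EY1 V
WEATHER  W EH1 DH ER0
WINDOW  W IH1 N D OW0
WINTER  W IH1 N T ER0
WOOD  W UH1 D
WOOL  W UH1 L
WORE  W AO1 R
WORLD  W ER1 L D
WORM  W ER1 M
WORMHOLE  W ER1 M HH OW2 L
YARD  Y AA1 R D
YELLOW  Y EH1 L OW0
YES  Y EH1 S
YOUNG  Y AH1 NG
ZERO  Z IH1 R OW0
ZOO  Z UW1
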