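BrighamYoung	7
FloridaState	0
Iowa	2
KansasState	3
NewMexico	7
TexasTech	3
PennState	2
SouthernCalifornia	8
ArizonaState	8
SanDiegoState	7
Baylor	3
NorthTexas	10
NorthernIllinois	6
Northwestern	2
WesternMichigan	6
Wisconsin	2
Wyoming	7
Auburn	9
Akron	6
VirginiaTech	1
Alabama	9
UCLA	8
Arizona	8
Utah	7
ArkansasState	10
NorthCarolinaState	0
BallState	6
Florida	9
BoiseState	11
BostonCollege	1
WestVirginia	1
BowlingGreenState	6
Michigan	2
Virginia	0
Buffalo	6
Syracuse	1
CentralFlorida	5
GeorgiaTech	0
CentralMichigan	6
Purdue	2
Colorado	3
ColoradoState	7
Connecticut	5
EasternMichigan	6
EastCarolina	4
Duke	0
FresnoState	11
OhioState	2
Houston	4
Rice	11
Idaho	10
Washington	8
Kansas	3
SouthernMethodist	11
Kent	6
Pittsburgh	1
Kentucky	9
Louisville	4
LouisianaTech	11
LouisianaMonroe	10
Minnesota	2
MiamiOhio	6
Vanderbilt	9
MiddleTennesseeState	10
Illinois	2
MississippiState	9
Memphis	4
Nevada	11
Oregon	8
NewMexicoState	10
SouthCarolina	9
Ohio	6
IowaState	3
SanJoseState	11
Nebraska	3
SouthernMississippi	4
Tennessee	9
Stanford	8
WashingtonState	8
Temple	1
Navy	5
TexasA&M	3
NotreDame	5
TexasElPaso	11
Oklahoma	3
Toledo	6
Tulane	4
Mississippi	9
Tulsa	11
NorthCarolina	0
UtahState	5
Army	4
Cincinnati	4
AirForce	7
Rutgers	1
Georgia	9
LouisianaState	9
LouisianaLafayette	10
Texas	3
Marshall	6
MichiganState	2
MiamiFlorida	1
Missouri	3
Clemson	0
NevadaLasVegas	7
WakeForest	0
Indiana	2
OklahomaState	3
OregonState	8
Maryland	0
TexasChristian	4
California	8
AlabamaBirmingham	4
Arkansas	9
Hawaii	11
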