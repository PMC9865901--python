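# Rice varieties with GNPP over 200 in the MBK germplasm database, with their
# published subpopulation, geographic origin and LAX1/GNP1 haplotype labels.
variety	subpopulation	origin	LAX1	GNP1
ZhongHan502	Japonica	China	T2	T6
Bg90-2	Intermediate	Sri Lanka	T6	T1
NingGeng28Hao	Japonica	China	T2	T1
YanGeng7Hao	Japonica	China	T5	T1
XiangQing	Japonica	China	T2	T1
C9083	Japonica	China	T2	T1
FUNAKIOMACHI	Japonica	Japan	T2	T1
HOUMANSHINDENINE	Japonica	Japan	T2	T1
KABASHIKO	Japonica	Japan	T2	T1
KAMEJI	Japonica	Japan	T2	T1
KAMENOO	Japonica	Japan	T2	T1
NingGeng24Hao	Japonica	China	T2	T1
RAIDEN	Japonica	Japan	T2	T1
WATARIBUNE1681	Japonica	Japan	T2	T1
CP231	Japonica	United States	T2	T1
Basmati370	Indica	India	T1	T5
Zhongchao123	Japonica	China	T2	T21
ChangShu-6-85	Japonica	China	T2	T1
LianGeng11Hao	Japonica	China	T2	T1
PuTe6Hao	Japonica	China	T2	T1
SongGeng15	Japonica	China	T2	T1
TASENSHO	Japonica	Japan	T2	T1
R162	Japonica	China	T2	T1
NingGeng35Hao	Japonica	China	T13	T1
SHINYAMADABO1	Japonica	Japan	T2	T1
GORIKI	Japonica	Japan	T2	T1
MANGOKU	Japonica	Japan	T2	T1
JC1	Indica	India	T3	T1
SEKIYAMA	Japonica	Japan	T2	T1
AMBARIKORI	Indica	Africa	T1	T3
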