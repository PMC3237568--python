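species	compartment	amount_nM	source	tags
AKT	cytosol	200.0		
AKT:PDK1:PIP3	cytosol	0.0		
AKT:PIP3	cytosol	0.0		
ASK1	cytosol	150.0		
ASK1:ROS	cytosol	0.0		
ASK1:p-AKT	cytosol	0.0		
ASK1Pase	cytosol	25.0		
ASK1Pase:p-ASK1	cytosol	0.0		
ASK1i	cytosol	0.0		
EGF	membrane	100.0		stimulus:EGF
EGF:EGF:EGFR:EGFR	cytosol	0.0		
EGF:EGF:Gab1:Grb2:p-EGFR:p-EGFR	cytosol	0.0		
EGF:EGF:Grb2:PI3K:PIP2:p-EGFR:p-EGFR:p-Gab1	cytosol	0.0		
EGF:EGF:Grb2:PI3K:RacGDP:p-EGFR:p-EGFR:p-Gab1	cytosol	0.0		
EGF:EGF:Grb2:PI3K:p-EGFR:p-EGFR:p-Gab1	cytosol	0.0		
EGF:EGF:Grb2:RasGDP:SOS:p-EGFR:p-EGFR:p-Shc	cytosol	0.0		
EGF:EGF:Grb2:SOS:p-EGFR:p-EGFR:p-ERK:p-Shc	cytosol	0.0		
EGF:EGF:Grb2:SOS:p-EGFR:p-EGFR:p-Shc	cytosol	0.0		
EGF:EGF:Grb2:p-EGFR:p-EGFR	cytosol	0.0		
EGF:EGF:Grb2:p-EGFR:p-EGFR:p-Gab1	cytosol	0.0		
EGF:EGF:Grb2:p-EGFR:p-EGFR:p-SOS:p-Shc	cytosol	0.0		
EGF:EGF:Shc:p-EGFR:p-EGFR	cytosol	0.0		
EGF:EGF:p-EGFR:p-EGFR	cytosol	0.0		
EGF:EGF:p-EGFR:p-EGFR:p-Shc	cytosol	0.0		
EGF:EGFR	cytosol	0.0		
EGFR	membrane	150.0		
EGFRi	cytosol	0.0		
ERK	cytosol	250.0		
ERK:p-MEK	cytosol	0.0		
ERKPase	cytosol	30.0		
ERKPase:p-ERK	cytosol	0.0		
Gab1	cytosol	60.0		
Grb2	cytosol	80.0		
Grb2:SOS	cytosol	0.0		
Grb2:p-SOS	cytosol	0.0		
MEK	cytosol	200.0		
MEK:p-Raf	cytosol	0.0		
MEKPase	cytosol	25.0		
MEKPase:p-MEK	cytosol	0.0		
MKK	cytosol	200.0		
MKK:p-ASK1	cytosol	0.0		
MKKPase	cytosol	25.0		
MKKPase:p-MKK	cytosol	0.0		
PDK1	cytosol	60.0		
PI3K	cytosol	50.0		
PIP2	cytosol	500.0		
PIP3	cytosol	0.0		
PIP3:PTEN	cytosol	0.0		
PIP3:p-AKT	cytosol	0.0		
PP2A	cytosol	30.0		
PP2A:p-AKT	cytosol	0.0		
PTEN	cytosol	50.0		
ROS	cytosol	0.0		
ROS:ROSscav	cytosol	0.0		
ROSscav	cytosol	80.0		
RacGDP	cytosol	150.0		
RacGTP	cytosol	0.0		
Raf	cytosol	150.0		
Raf:RasGTP	cytosol	0.0		
RafPase	cytosol	25.0		
RafPase:p-Raf	cytosol	0.0		
RasGAP	cytosol	25.0		
RasGAP:RasGTP	cytosol	0.0		
RasGDP	cytosol	200.0		
RasGTP	cytosol	0.0		
Rsv001	cytosol	0.0		
Rsv002	cytosol	0.0		
Rsv003	cytosol	0.0		
Rsv004	cytosol	0.0		
Rsv005	cytosol	0.0		
Rsv006	cytosol	0.0		
Rsv007	cytosol	0.0		
Rsv008	cytosol	0.0		
Rsv009	cytosol	0.0		
Rsv010	cytosol	0.0		
Rsv011	cytosol	0.0		
Rsv012	cytosol	0.0		
Rsv013	cytosol	0.0		
Rsv014	cytosol	0.0		
Rsv015	cytosol	0.0		
Rsv016	cytosol	0.0		
Rsv017	cytosol	0.0		
Rsv018	cytosol	0.0		
Rsv019	cytosol	0.0		
Rsv020	cytosol	0.0		
Rsv021	cytosol	0.0		
Rsv022	cytosol	0.0		
Rsv023	cytosol	0.0		
Rsv024	cytosol	0.0		
Rsv025	cytosol	0.0		
Rsv026	cytosol	0.0		
Rsv027	cytosol	0.0		
Rsv028	cytosol	0.0		
Rsv029	cytosol	0.0		
Rsv030	cytosol	0.0		
Rsv031	cytosol	0.0		
Rsv032	cytosol	0.0		
Rsv033	cytosol	0.0		
Rsv034	cytosol	0.0		
Rsv035	cytosol	0.0		
Rsv036	cytosol	0.0		
Rsv037	cytosol	0.0		
Rsv038	cytosol	0.0		
Rsv039	cytosol	0.0		
Rsv040	cytosol	0.0		
Rsv041	cytosol	0.0		
Rsv042	cytosol	0.0		
Rsv043	cytosol	0.0		
Rsv044	cytosol	0.0		
Rsv045	cytosol	0.0		
Rsv046	cytosol	0.0		
Rsv047	cytosol	0.0		
Rsv048	cytosol	0.0		
Rsv049	cytosol	0.0		
Rsv050	cytosol	0.0		
Rsv051	cytosol	0.0		
Rsv052	cytosol	0.0		
Rsv053	cytosol	0.0		
Rsv054	cytosol	0.0		
Rsv055	cytosol	0.0		
Rsv056	cytosol	0.0		
Rsv057	cytosol	0.0		
Rsv058	cytosol	0.0		
Rsv059	cytosol	0.0		
Rsv060	cytosol	0.0		
Rsv061	cytosol	0.0		
Rsv062	cytosol	0.0		
Rsv063	cytosol	0.0		
Rsv064	cytosol	0.0		
Rsv065	cytosol	0.0		
Rsv066	cytosol	0.0		
Rsv067	cytosol	0.0		
Rsv068	cytosol	0.0		
Rsv069	cytosol	0.0		
Rsv070	cytosol	0.0		
Rsv071	cytosol	0.0		
Rsv072	cytosol	0.0		
Rsv073	cytosol	0.0		
Rsv074	cytosol	0.0		
Rsv075	cytosol	0.0		
Rsv076	cytosol	0.0		
Rsv077	cytosol	0.0		
Rsv078	cytosol	0.0		
SOS	cytosol	40.0		
Shc	cytosol	200.0		
p-AKT	cytosol	0.0		
p-AKT:p-ASK1	cytosol	0.0		
p-ASK1	cytosol	0.0		
p-ERK	cytosol	0.0		
p-Gab1	cytosol	0.0		
p-MEK	cytosol	0.0		
p-MKK	cytosol	0.0		
p-MKK:p38	cytosol	0.0		
p-Raf	cytosol	0.0		
p-SOS	cytosol	0.0		
p-Shc	cytosol	0.0		
p-p38	cytosol	0.0		
p-p38:p38Pase	cytosol	0.0		
p38	cytosol	250.0		
p38Pase	cytosol	30.0		
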