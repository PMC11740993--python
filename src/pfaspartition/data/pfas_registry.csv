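acronym,name,group,fc_n,total_carbons,formula,species,hydrophobic,headgroup,casrn
PFBA,perfluorobutanoic acid,PFCA,3,4,C4F7O2,anion,False,carboxylate,375-22-4
PFPeA,perfluoropentanoic acid,PFCA,4,5,C5F9O2,anion,False,carboxylate,
PFHxA,perfluorohexanoic acid,PFCA,5,6,C6F11O2,anion,False,carboxylate,307-24-4
PFHpA,perfluoroheptanoic acid,PFCA,6,7,C7F13O2,anion,False,carboxylate,
PFOA,perfluorooctanoic acid,PFCA,7,8,C8F15O2,anion,False,carboxylate,335-67-1
PFNA,perfluorononanoic acid,PFCA,8,9,C9F17O2,anion,False,carboxylate,375-95-1
PFDA,perfluorodecanoic acid,PFCA,9,10,C10F19O2,anion,False,carboxylate,335-76-2
PFUnA,perfluoroundecanoic acid,PFCA,10,11,C11F21O2,anion,True,carboxylate,
PFDoA,perfluorododecanoic acid,PFCA,11,12,C12F23O2,anion,True,carboxylate,
PFTrDA,perfluorotridecanoic acid,PFCA,12,13,C13F25O2,anion,True,carboxylate,
PFTeDA,perfluorotetradecanoic acid,PFCA,13,14,C14F27O2,anion,True,carboxylate,
PFHxDA,perfluorohexadecanoic acid,PFCA,15,16,C16F31O2,anion,True,carboxylate,
PFBS,perfluorobutanesulfonic acid,PFSA,4,4,C4F9O3S,anion,False,sulfonate,375-73-5
PFPeS,perfluoropentansulfonic acid,PFSA,5,5,C5F11O3S,anion,False,sulfonate,
PFHxS,perfluorohexanesulfonic acid,PFSA,6,6,C6F13O3S,anion,False,sulfonate,355-46-4
PFHpS,perfluoroheptanesulfonic acid,PFSA,7,7,C7F15O3S,anion,False,sulfonate,
PFOS,perfluorooctanesulfonic acid,PFSA,8,8,C8F17O3S,anion,False,sulfonate,1763-23-1
PFNS,perfluorononanesulfonic acid,PFSA,9,9,C9F19O3S,anion,False,sulfonate,
PFDS,perfluorodecanesulfonic acid,PFSA,10,10,C10F21O3S,anion,True,sulfonate,
PFDoS,perfluorododecanesulfonic acid,PFSA,12,12,C12F25O3S,anion,True,sulfonate,
4:2 FTS,"1H,1H,2H,2H-perfluorohexanesulfonic acid",FTS,4,6,C6H4F9O3S,anion,False,sulfonate,
6:2 FTS,"1H,1H,2H,2H-perfluorooctanesulfonic acid",FTS,6,8,C8H4F13O3S,anion,False,sulfonate,
8:2 FTS,"1H,1H,2H,2H-perfluorodecanesulfonic acid",FTS,8,10,C10H4F17O3S,anion,False,sulfonate,
10:2 FTS,"1H,1H,2H,2H-perfluorododecanesulfonic acid",FTS,10,12,C12H4F21O3S,anion,True,sulfonate,
PFOSA,perfluorooctanesulfonamide,PFOSAm,8,8,C8H2F17NO2S,neutral,True,sulfonamide,754-91-6
NMeFOSA,N-methyl perfluorooctanesulfonamide,PFOSAm,8,9,C9H4F17NO2S,neutral,False,sulfonamide,
NEtFOSA,N-ethyl perfluorooctanesulfonamide,PFOSAm,8,10,C10H6F17NO2S,neutral,False,sulfonamide,
NMeFOSAA,N-methyl perfluorooctanesulfonamidoacetic acid,PFOSAA,8,11,C11H5F17NO4S,anion,False,carboxylate,
NEtFOSAA,N-ethyl perfluorooctanesulfonamidoacetic acid,PFOSAA,8,12,C12H7F17NO4S,anion,False,carboxylate,
FOSAA,perfluorooctanesulfonamidoacetic acid,PFOSAA,8,10,C10H3F17NO4S,anion,False,carboxylate,
NMeFOSE,N-methyl perfluorooctanesulfonamidoethanol,PFOSE,8,11,C11H8F17NO3S,neutral,False,alcohol,
NEtFOSE,N-ethyl perfluorooctanesulfonamidoethanol,PFOSE,8,12,C12H10F17NO3S,neutral,False,alcohol,
HFPO-DA,hexafluoropropylene oxide dimer acid,PFECA,5,6,C6F11O3,anion,False,carboxylate,13252-13-6
ADONA,"4,8-dioxa-3H-perfluorononanoic acid",PFECA,6,7,C7HF12O4,anion,False,carboxylate,
PFMPA,perfluoro-3-methoxypropanoic acid,PFECA,3,4,C4F7O3,anion,False,carboxylate,
PFMBA,perfluoro-4-methoxybutanoic acid,PFECA,4,5,C5F9O3,anion,False,carboxylate,
NFDHA,"nonafluoro-3,6-dioxaheptanoic acid",PFECA,4,5,C5F9O4,anion,False,carboxylate,
9Cl-PF3ONS,9-chlorohexadecafluoro-3-oxanonane-1-sulfonic acid,ESA,8,8,C8ClF16O4S,anion,True,sulfonate,
11Cl-PF3OUdS,11-chloroeicosafluoro-3-oxaundecane-1-sulfonic acid,ESA,10,10,C10ClF20O4S,anion,True,sulfonate,
PFEESA,perfluoro(2-ethoxyethane)sulfonic acid,ESA,4,4,C4F9O4S,anion,False,sulfonate,
3:3 FTCA,3-perfluoropropyl propanoic acid,FTCA,3,6,C6H4F7O2,anion,False,carboxylate,
5:3 FTCA,"2H,2H,3H,3H-perfluorooctanoic acid",FTCA,5,8,C8H4F11O2,anion,False,carboxylate,
7:3 FTCA,3-perfluoroheptyl propanoic acid,FTCA,7,10,C10H4F15O2,anion,False,carboxylate,
6:2 FTCA,2-(perfluorohexyl)ethanoic acid,FTCA,6,8,C8H2F13O2,anion,False,carboxylate,
8:2 FTCA,2-(perfluorooctyl)ethanoic acid,FTCA,8,10,C10H2F17O2,anion,False,carboxylate,
10:2 FTCA,2-(perfluorodecyl)ethanoic acid,FTCA,10,12,C12H2F21O2,anion,True,carboxylate,
6:2 FTUCA,6:2 fluorotelomer unsaturated carboxylic acid,FTUCA,6,8,C8HF12O2,anion,False,carboxylate,
8:2 FTUCA,8:2 fluorotelomer unsaturated carboxylic acid,FTUCA,8,10,C10HF16O2,anion,False,carboxylate,
6:2 diPAP,6:2 fluorotelomer phosphate diester,diPAP,12,16,C16H8F26O4P,anion,True,phosphate,
8:2 diPAP,8:2 fluorotelomer phosphate diester,diPAP,16,20,C20H8F34O4P,anion,True,phosphate,
diSAmPAP,EtFOSE-based phosphate diester,diPAP,16,24,C24H18F34N2O8PS2,anion,True,phosphate,
8Cl-PFOS,8-chloro-perfluorooctanesulfonic acid,Other,8,8,C8ClF16O3S,anion,False,sulfonate,
PFEtCHxS,perfluoro-p-ethylcyclohexylsulfonic acid,Other,8,8,C8F15O3S,anion,False,sulfonate,
FBSA,perfluorobutanesulfonamide,Other,4,4,C4H2F9NO2S,neutral,False,sulfonamide,
FHxSA,perfluorohexanesulfonamide,Other,6,6,C6H2F13NO2S,neutral,False,sulfonamide,
PFHxSaAm,perfluorohexane sulfonamido amine,Other,6,11,C11H13F13N2O2S,zwitterion,False,betaine/zwitterion,
6:2 FtSaB,6:2 fluorotelomer sulfonamide betaine,Other,6,15,C15H19F13N2O4S,zwitterion,False,betaine/zwitterion,
N-TAmP-FHxSA,N-trimethylammoniopropyl perfluorohexane sulfonamide,Other,6,12,C12H15F13N2O2S,zwitterion,False,betaine/zwitterion,
5:3 FTB,5:3 fluorotelomer betaine,Other,5,12,C12H14F11NO2,zwitterion,False,betaine/zwitterion,
5:1:2 FTB,5:1:2 fluorotelomer betaine,Other,6,12,C12H13F12NO2,zwitterion,False,betaine/zwitterion,
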