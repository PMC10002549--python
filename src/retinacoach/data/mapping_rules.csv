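dialect,raw_label,target
odir,normal fundus,C0
odir,age-related macular degeneration,C1
odir,dry age-related macular degeneration,C1
odir,wet age-related macular degeneration,C1
odir,mild nonproliferative retinopathy,C2
odir,moderate non proliferative retinopathy,C3
odir,severe nonproliferative retinopathy,C4
odir,proliferative diabetic retinopathy,C5
odir,severe proliferative diabetic retinopathy,C5
odir,glaucoma,C6
odir,hypertensive retinopathy,C7
odir,pathological myopia,C8
odir,tessellated fundus,C9
odir,vitreous degeneration,C10
odir,branch retinal vein occlusion,C11
odir,drusen,C14
odir,epiretinal membrane,C15
odir,epiretinal membrane over the macula,C15
odir,macular epiretinal membrane,C15
odir,optic disc edema,C18
odir,myelinated nerve fibers,C19
odir,rhegmatogenous retinal detachment,C22
odir,macular hole,C23
odir,chorioretinal atrophy,C24
odir,cataract,C25
odir,refractive media opacity,C25
odir,central serous chorioretinopathy,C27
odir,post laser photocoagulation,C29
odir,laser spot,C29
odir,central retinal artery occlusion,C31
odir,branch retinal artery occlusion (brao),C31
odir,central retinal vein occlusion,C32
odir,retinitis pigmentosa,C33
rfmid,ARMD,C1
rfmid,MYA,C8
rfmid,TSLN,C9
rfmid,AH,C10
rfmid,BRVO,C11
rfmid,ODC,C13
rfmid,DN,C14
rfmid,ERM,C15
rfmid,TD,C16
rfmid,ODE,C18
rfmid,MNF,C19
rfmid,MHL,C23
rfmid,CB,C24
rfmid,MH,C25
rfmid,CSR,C27
rfmid,LS,C29
rfmid,CRAO,C31
rfmid,BRAO,C31
rfmid,CRVO,C32
rfmid,RP,C33
rfmid,PRH,C34
rfmid,EDN,C35
rfmid,CWS,C37
rfmid,TV,C38
jsiec,0.0.Normal,C0
jsiec,6.Maculopathy,C1
jsiec,0.3.DR1,C2
jsiec,1.0.DR2,C3
jsiec,1.1.DR3,C5
jsiec,9.Pathological myopia,C8
jsiec,0.1.Tessellated fundus,C9
jsiec,18.Vitreous particles,C10
jsiec,2.0.BRVO,C11
jsiec,5.1.VKH disease,C12
jsiec,0.2.Large optic cup,C13
jsiec,7.ERM,C15
jsiec,13.Dragged Disc,C16
jsiec,14.Congenital disc abnormality,C17
jsiec,12.Disc swelling and elevation,C18
jsiec,17.Myelinated nerve fiber,C19
jsiec,15.1.Bietti crystalline dystrophy,C20
jsiec,16.Peripheral retinal degeneration and break,C21
jsiec,4.Rhegmatogenous RD,C22
jsiec,8.MH,C23
jsiec,24.Chorioretinal atrophy-coloboma,C24
jsiec,29.0.Blur fundus without PDR,C25
jsiec,29.1.Blur fundus with suspected PDR,C26
jsiec,5.0.CSCR,C27
jsiec,19.Fundus neoplasm,C28
jsiec,27.Laser Spots,C29
jsiec,28.Silicon oil in eye,C30
jsiec,3.RAO,C31
jsiec,2.1.CRVO,C32
jsiec,15.0.Retinitis pigmentosa,C33
jsiec,25.Preretinal hemorrhage,C34
jsiec,20.Massive hard exudates,C35
jsiec,21.Yellow-white spots-flecks,C36
jsiec,22.Cotton-wool spots,C37
jsiec,23.Vessel tortuosity,C38
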