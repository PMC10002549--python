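code,display_name,topic,retained,allocation_level,supplementary_rare
C0,normal,T1,1,1,0
C1,age-related macular degeneration,T2,1,1,0
C2,mild nonproliferative diabetic retinopathy,,1,0,0
C3,moderate nonproliferative diabetic retinopathy,,1,0,0
C4,severe nonproliferative diabetic retinopathy,,1,0,0
C5,proliferative diabetic retinopathy,,1,0,0
C6,glaucoma,T4,1,1,0
C7,hypertensive retinopathy,T3,1,1,0
C8,pathological myopia,T2,1,1,0
C9,tessellated fundus,T1,1,1,0
C10,vitreous degeneration,T6,1,1,0
C11,branch retinal vein occlusion,T3,1,1,0
C12,Vogt-Koyanagi-Harada disease,,0,0,1
C13,large optic cup,T4,1,1,0
C14,drusen,T2,1,1,0
C15,epiretinal membrane,T2,1,1,0
C16,dragged disc,,0,0,1
C17,congenital disc abnormality,,0,0,1
C18,optic disc edema,T4,1,1,0
C19,myelinated nerve fibers,T4,1,1,0
C20,Bietti crystalline dystrophy,,0,0,1
C21,peripheral retinal degeneration and break,,0,0,1
C22,rhegmatogenous retinal detachment,T5,1,1,0
C23,macular hole,,0,0,1
C24,chorioretinal atrophy-coloboma,,0,0,1
C25,refractive media opacity,T6,1,1,0
C26,blur fundus with suspected PDR,,0,0,1
C27,central serous chorioretinopathy,T2,1,1,0
C28,fundus neoplasm,,0,0,1
C29,laser spots,T5,1,1,0
C30,silicone oil in eye,,0,0,1
C31,retinal artery occlusion,,0,0,1
C32,central retinal vein occlusion,T3,1,1,0
C33,retinitis pigmentosa,,0,0,1
C34,preretinal hemorrhage,,0,0,1
C35,massive hard exudates,,0,0,1
C36,yellow-white spots-flecks,,0,0,1
C37,cotton-wool spots,,0,0,1
C38,vessel tortuosity,,0,0,1
DR,diabetic retinopathy,T3,0,1,0
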