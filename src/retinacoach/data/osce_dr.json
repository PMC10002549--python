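{
  "condition": "DR",
  "title": "Diabetic retinopathy OSCE evaluation file",
  "sections": {
    "clinical_signs": [
      "Microaneurysms",
      "Dot-blot hemorrhages",
      "Hard exudates",
      "Cotton-wool spots",
      "Venous beading",
      "Intraretinal microvascular anomalies",
      "Neovascularisation of the disc",
      "Neovascularisation elsewhere",
      "Preretinal hemorrhage",
      "Vitreous hemorrhage",
      "Tractional retinal detachment",
      "Laser spots"
    ],
    "differential_macular_edema": [
      "Hypertensive retinopathy",
      "Central retinal vein occlusion",
      "Branch retinal vein occlusion",
      "Choroidal neovascular membrane",
      "Macular edema secondary to epiretinal membrane",
      "Ruptured microaneurysm",
      "Irvine Gass syndrome",
      "Post uveitic macular edema"
    ],
    "differential_retinopathy": [
      "Central retinal vein occlusion",
      "Hemiretinal vein occlusion",
      "Branch retinal vein occlusion",
      "Hypertensive retinopathy",
      "Ocular ischemic syndrome",
      "Terson syndrome",
      "Valsalva retinopathy",
      "Sickle cell retinopathy",
      "Post-traumatic retinal bleed",
      "Retinal macroaneurysm",
      "Retinopathy in thalassemia"
    ],
    "management_macular_edema": [
      "Observation",
      "Intravitreal anti-VEGF"
    ],
    "management_retinopathy": [
      "Observation",
      "Intravitreal anti-VEGF",
      "Panfundus laser photocoagulation",
      "Vitrectomy"
    ]
  }
}
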