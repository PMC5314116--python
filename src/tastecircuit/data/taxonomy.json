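{
  "regions": [
    {"label": "thalamus", "hemisphere": "left", "volume": 120},
    {"label": "dorsal_anterior_insula", "hemisphere": "left", "volume": 60},
    {"label": "ventral_anterior_insula", "hemisphere": "left", "volume": 55},
    {"label": "posterior_insula", "hemisphere": "left", "volume": 70},
    {"label": "frontal_operculum", "hemisphere": "left", "volume": 45},
    {"label": "substantia_nigra", "hemisphere": "left", "volume": 25},
    {"label": "central_nucleus_amygdala", "hemisphere": "left", "volume": 20},
    {"label": "basolateral_amygdala", "hemisphere": "left", "volume": 30},
    {"label": "medial_OFC", "hemisphere": "left", "volume": 80},
    {"label": "middle_OFC", "hemisphere": "left", "volume": 75},
    {"label": "gyrus_rectus", "hemisphere": "left", "volume": 65},
    {"label": "inferior_OFC", "hemisphere": "left", "volume": 70},
    {"label": "ventral_striatum", "hemisphere": "left", "volume": 50},
    {"label": "medial_PFC", "hemisphere": "left", "volume": 110},
    {"label": "hypothalamus", "hemisphere": "left", "volume": 18},
    {"label": "anterior_cingulate", "hemisphere": "left", "volume": 95},
    {"label": "thalamus", "hemisphere": "right", "volume": 118},
    {"label": "dorsal_anterior_insula", "hemisphere": "right", "volume": 62},
    {"label": "ventral_anterior_insula", "hemisphere": "right", "volume": 54},
    {"label": "posterior_insula", "hemisphere": "right", "volume": 72},
    {"label": "frontal_operculum", "hemisphere": "right", "volume": 44},
    {"label": "substantia_nigra", "hemisphere": "right", "volume": 26},
    {"label": "central_nucleus_amygdala", "hemisphere": "right", "volume": 21},
    {"label": "basolateral_amygdala", "hemisphere": "right", "volume": 29},
    {"label": "medial_OFC", "hemisphere": "right", "volume": 82},
    {"label": "middle_OFC", "hemisphere": "right", "volume": 74},
    {"label": "gyrus_rectus", "hemisphere": "right", "volume": 66},
    {"label": "inferior_OFC", "hemisphere": "right", "volume": 71},
    {"label": "ventral_striatum", "hemisphere": "right", "volume": 51},
    {"label": "medial_PFC", "hemisphere": "right", "volume": 108},
    {"label": "hypothalamus", "hemisphere": "right", "volume": 19},
    {"label": "anterior_cingulate", "hemisphere": "right", "volume": 96}
  ]
}
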