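{
  "subclasses": [
    {"name": "Temporal", "class_label": "sensory",
     "descriptors": ["flickering", "quivering", "pulsing", "throbbing", "beating", "pounding"]},
    {"name": "Spatial", "class_label": "sensory",
     "descriptors": ["jumping", "flashing", "shooting"]},
    {"name": "Punctuate pressure", "class_label": "sensory",
     "descriptors": ["pricking", "boring", "drilling", "stabbing", "lancinating"]},
    {"name": "Incisive pressure", "class_label": "sensory",
     "descriptors": ["sharp", "cutting", "lacerating"]},
    {"name": "Constrictive pressure", "class_label": "sensory",
     "descriptors": ["pinching", "pressing", "gnawing", "cramping", "crushing"]},
    {"name": "Traction pressure", "class_label": "sensory",
     "descriptors": ["tugging", "pulling", "wrenching"]},
    {"name": "Thermal", "class_label": "sensory",
     "descriptors": ["hot", "burning", "scalding", "searing"]},
    {"name": "Brightness", "class_label": "sensory",
     "descriptors": ["tingling", "itchy", "smarting", "stinging"]},
    {"name": "Dullness", "class_label": "sensory",
     "descriptors": ["dull", "sore", "hurting", "aching", "heavy"]},
    {"name": "Sensory miscellaneous", "class_label": "sensory",
     "descriptors": ["tender", "taut", "rasping", "splitting"]},
    {"name": "Tension", "class_label": "affective",
     "descriptors": ["tiring", "exhausting"]},
    {"name": "Autonomic", "class_label": "affective",
     "descriptors": ["sickening", "suffocating"]},
    {"name": "Fear", "class_label": "affective",
     "descriptors": ["fearful", "frightful"]},
    {"name": "Punishment", "class_label": "affective",
     "descriptors": ["terrifying", "punishing", "grueling", "cruel", "vicious", "killing"]},
    {"name": "Affective-evaluative-sensory miscellaneous", "class_label": "affective",
     "descriptors": ["wretched", "blinding"]},
    {"name": "Evaluative", "class_label": "evaluative",
     "descriptors": ["annoying", "troublesome", "miserable", "intense", "unbearable"]},
    {"name": "Supplementary a", "class_label": "supplementary",
     "descriptors": ["spreading", "radiating", "penetrating", "piercing"]},
    {"name": "Supplementary b", "class_label": "supplementary",
     "descriptors": ["tight", "numb", "drawing", "squeezing", "tearing"]},
    {"name": "Supplementary c", "class_label": "supplementary",
     "descriptors": ["cool", "cold", "freezing"]},
    {"name": "Supplementary d", "class_label": "supplementary",
     "descriptors": ["nagging", "nauseating", "agonizing", "dreadful", "torturing"]}
  ]
}
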