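[
 {"canonical": "chest pain", "synonyms": ["chest pain", "chest discomfort", "chest heaviness", "chest tightness", "retrosternal pain"]},
 {"canonical": "shortness of breath", "synonyms": ["shortness of breath", "sob", "dyspnea", "difficulty breathing", "breathlessness"]},
 {"canonical": "nausea or vomiting", "synonyms": ["nausea or vomiting", "nausea", "vomiting", "nausea and vomiting"]},
 {"canonical": "sweating or diaphoresis", "synonyms": ["sweating or diaphoresis", "sweating", "diaphoresis", "excessive sweating"]},
 {"canonical": "abdominal pain or discomfort", "synonyms": ["abdominal pain or discomfort", "abdominal pain", "abdominal discomfort", "epigastric pain"]},
 {"canonical": "arm pain", "synonyms": ["arm pain", "left arm pain", "pain in arm"]},
 {"canonical": "ghabrahat", "synonyms": ["ghabrahat", "ghabrat"]},
 {"canonical": "weakness", "synonyms": ["weakness", "generalized weakness", "lethargy"]},
 {"canonical": "shoulder pain", "synonyms": ["shoulder pain", "left shoulder pain"]},
 {"canonical": "palpitations", "synonyms": ["palpitations", "palpitation"]},
 {"canonical": "back pain", "synonyms": ["back pain"]},
 {"canonical": "altered mental status", "synonyms": ["altered mental status", "confusion", "drowsiness"]},
 {"canonical": "dizziness", "synonyms": ["dizziness", "giddiness", "vertigo", "lightheadedness"]},
 {"canonical": "jaw pain", "synonyms": ["jaw pain"]},
 {"canonical": "orthopnea", "synonyms": ["orthopnea"]},
 {"canonical": "neck pain", "synonyms": ["neck pain"]},
 {"canonical": "throat pain", "synonyms": ["throat pain", "sore throat"]},
 {"canonical": "swelling", "synonyms": ["swelling", "pedal edema", "leg swelling"]}
]
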