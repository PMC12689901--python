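{
  "Obstipation": ["Verstopfung", "verstopft", "Obstipation"],
  "Husten": ["husten", "gehustet", "hustet", "Hustenreiz"],
  "Dyspnoe": ["Luftnot", "Atemnot", "Kurzatmigkeit", "kurzatmig"],
  "Übelkeit": ["Nausea", "übel"],
  "Erbrechen": ["erbrochen", "Emesis"],
  "Fieber": ["fiebrig", "febril", "Pyrexie"],
  "Schwindel": ["schwindelig", "schwindlig", "Vertigo"],
  "Kopfschmerzen": ["Kopfschmerz", "Cephalgie", "Zephalgie"],
  "Diarrhoe": ["Durchfall", "Diarrhö", "Diarrhoen"],
  "Müdigkeit": ["Fatigue", "Abgeschlagenheit", "müde"],
  "Schwellung": ["geschwollen", "Schwellungen"],
  "Rötung": ["gerötet", "Rötungen"]
}
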