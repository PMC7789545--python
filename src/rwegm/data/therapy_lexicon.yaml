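# PARP-inhibitor lexicon for therapy discussion/prescription extraction.
# "lyparza" is kept alongside the usual brand spelling "lynparza".
generic: [olaparib, rucaparib, niraparib]
abbreviations: [parp, parpi]
brands: [lynparza, lyparza, rubraca, zejula]
current_medication_headers: ["current medications?", "medications? list"]
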