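# L2 — All relations whose subject and object both carry MeSH descriptor
# IDs (the trusted relation set used to calibrate the PMI threshold).
SELECT ?subject ?subjectID ?prop ?object ?objectID WHERE {
  ?subject wdt:P486 ?subjectID .
  ?object wdt:P486 ?objectID .
  ?subject ?prop ?object .
}
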