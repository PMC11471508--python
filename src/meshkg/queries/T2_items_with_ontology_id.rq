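# T2 — All items holding an external identifier of one ontology.
# Substitute the ontology's ID property for P699 (Disease Ontology ID).
SELECT ?subject ?subjectID WHERE {
  ?subject wdt:P699 ?subjectID .
}
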