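# T4 — Properties linking items of one ontology to items of another.
# Substitute P699 / P686 for the two ontologies' ID properties.
SELECT ?subject ?subjectID ?prop ?object ?objectID WHERE {
  ?subject wdt:P699 ?subjectID .
  ?object wdt:P686 ?objectID .
  ?subject ?prop ?object .
}
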