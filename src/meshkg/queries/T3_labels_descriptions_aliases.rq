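# T3 — Labels, descriptions and aliases (with language tags) of every item
# aligned to one ontology. Substitute the ontology's ID property for P699.
SELECT ?subject ?subjectID ?property ?object ?language WHERE {
  ?subject wdt:P699 ?subjectID .
  VALUES ?property { rdfs:label schema:description skos:altLabel }
  ?subject ?property ?object .
  BIND(LANG(?object) AS ?language)
}
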