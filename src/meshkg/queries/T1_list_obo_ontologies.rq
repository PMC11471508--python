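# T1 — List OBO ontologies represented in the knowledge graph that carry
# both a URI ("exact match") and a dedicated external-identifier property.
# Run against a Wikidata-style SPARQL endpoint; execution is out of scope
# for this package (results are ingested as SPARQL SELECT result JSON).
SELECT ?ontology ?uri ?idProperty WHERE {
  ?ontology wdt:P31 wd:Q324254 ;          # instance of: ontology
            wdt:P361 wd:Q4117183 ;        # part of: OBO Foundry
            wdt:P2888 ?uri ;              # exact match: ontology URI
            wdt:P1687 ?idProperty .       # Wikidata property for concept IDs
}
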