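# L3 — A random sample of 1000 statements between MeSH-aligned items that
# carry no reference (no prov:wasDerivedFrom on the statement node).
SELECT ?subject ?subjectID ?prop ?object ?objectID WHERE {
  ?subject wdt:P486 ?subjectID .
  ?object wdt:P486 ?objectID .
  ?subject ?p ?statement .
  ?prop wikibase:claim ?p ;
        wikibase:statementProperty ?ps .
  ?statement ?ps ?object .
  FILTER NOT EXISTS { ?statement prov:wasDerivedFrom ?ref . }
}
LIMIT 1000
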