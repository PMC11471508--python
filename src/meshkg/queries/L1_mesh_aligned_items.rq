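# L1 — All items aligned to MeSH via a MeSH descriptor ID claim.
SELECT ?subject ?subjectID WHERE {
  ?subject wdt:P486 ?subjectID .
}
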