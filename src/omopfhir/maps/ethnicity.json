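{
  "resourceType": "ConceptMap",
  "id": "ethnicity",
  "name": "OMOPEthnicityToOMBEthnicityCategory",
  "status": "active",
  "group": [
    {
      "source": "urn:omopfhir:omop-concept-id",
      "target": "urn:oid:2.16.840.1.113883.6.238",
      "element": [
        {"code": "38003563", "target": [{"code": "2135-2", "display": "Hispanic or Latino", "equivalence": "equivalent"}]},
        {"code": "38003564", "target": [{"code": "2186-5", "display": "Not Hispanic or Latino", "equivalence": "equivalent"}]}
      ]
    }
  ]
}
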