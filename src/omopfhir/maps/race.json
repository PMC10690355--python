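{
  "resourceType": "ConceptMap",
  "id": "race",
  "name": "OMOPRaceToOMBRaceCategory",
  "status": "active",
  "group": [
    {
      "source": "urn:omopfhir:omop-concept-id",
      "target": "urn:oid:2.16.840.1.113883.6.238",
      "element": [
        {"code": "8527", "target": [{"code": "2106-3", "display": "White", "equivalence": "equivalent"}]},
        {"code": "8516", "target": [{"code": "2054-5", "display": "Black or African American", "equivalence": "equivalent"}]},
        {"code": "8515", "target": [{"code": "2028-9", "display": "Asian", "equivalence": "equivalent"}]},
        {"code": "8657", "target": [{"code": "1002-5", "display": "American Indian or Alaska Native", "equivalence": "equivalent"}]},
        {"code": "8557", "target": [{"code": "2076-8", "display": "Native Hawaiian or Other Pacific Islander", "equivalence": "equivalent"}]}
      ]
    }
  ]
}
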