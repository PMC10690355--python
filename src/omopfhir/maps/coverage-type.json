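{
  "resourceType": "ConceptMap",
  "id": "coverage-type",
  "name": "OMOPPayerConceptToPayerType",
  "status": "active",
  "group": [
    {
      "source": "urn:omopfhir:omop-concept-id",
      "target": "urn:omopfhir:payer-type",
      "element": [
        {"code": "1000001", "target": [{"code": "MEDICARE", "display": "Medicare", "equivalence": "equivalent"}]},
        {"code": "1000002", "target": [{"code": "MEDICAID", "display": "Medicaid", "equivalence": "equivalent"}]},
        {"code": "1000003", "target": [{"code": "COMMERCIAL", "display": "Commercial insurance", "equivalence": "equivalent"}]},
        {"code": "1000004", "target": [{"code": "SELFPAY", "display": "Self-pay", "equivalence": "equivalent"}]}
      ]
    }
  ]
}
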