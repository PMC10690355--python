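{
  "resourceType": "ConceptMap",
  "id": "visit-class",
  "name": "OMOPVisitConceptToActEncounterCode",
  "status": "active",
  "group": [
    {
      "source": "urn:omopfhir:omop-concept-id",
      "target": "http://terminology.hl7.org/CodeSystem/v3-ActCode",
      "element": [
        {"code": "9201", "target": [{"code": "IMP", "display": "inpatient encounter", "equivalence": "equivalent"}]},
        {"code": "9202", "target": [{"code": "AMB", "display": "ambulatory", "equivalence": "equivalent"}]},
        {"code": "9203", "target": [{"code": "EMER", "display": "emergency", "equivalence": "equivalent"}]}
      ]
    }
  ]
}
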