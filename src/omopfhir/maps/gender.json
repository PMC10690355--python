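{
  "resourceType": "ConceptMap",
  "id": "gender",
  "name": "OMOPGenderToAdministrativeGender",
  "status": "active",
  "group": [
    {
      "source": "urn:omopfhir:omop-concept-id",
      "target": "http://hl7.org/fhir/administrative-gender",
      "element": [
        {"code": "8507", "target": [{"code": "male", "display": "Male", "equivalence": "equivalent"}]},
        {"code": "8532", "target": [{"code": "female", "display": "Female", "equivalence": "equivalent"}]},
        {"code": "8521", "target": [{"code": "other", "display": "Other", "equivalence": "equivalent"}]},
        {"code": "8551", "target": [{"code": "unknown", "display": "Unknown", "equivalence": "equivalent"}]}
      ]
    }
  ]
}
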