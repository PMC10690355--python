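{
  "resourceType": "ConceptMap",
  "id": "birthsex",
  "name": "OMOPGenderToUSCoreBirthSex",
  "status": "active",
  "group": [
    {
      "source": "urn:omopfhir:omop-concept-id",
      "target": "http://terminology.hl7.org/CodeSystem/v3-AdministrativeGender",
      "element": [
        {"code": "8507", "target": [{"code": "M", "display": "Male", "equivalence": "equivalent"}]},
        {"code": "8532", "target": [{"code": "F", "display": "Female", "equivalence": "equivalent"}]}
      ]
    }
  ]
}
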