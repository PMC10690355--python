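{
  "resourceType": "ConceptMap",
  "id": "smoking-status",
  "name": "SmokingCategoryToSNOMEDSmokingStatus",
  "status": "active",
  "group": [
    {
      "source": "urn:omopfhir:smoking-category",
      "target": "http://snomed.info/sct",
      "element": [
        {"code": "current-every-day", "target": [{"code": "449868002", "display": "Smokes tobacco daily", "equivalence": "equivalent"}]},
        {"code": "current-some-day", "target": [{"code": "428041000124106", "display": "Occasional tobacco smoker", "equivalence": "equivalent"}]},
        {"code": "former", "target": [{"code": "8517006", "display": "Ex-smoker", "equivalence": "equivalent"}]},
        {"code": "never", "target": [{"code": "266919005", "display": "Never smoked tobacco", "equivalence": "equivalent"}]},
        {"code": "current-status-unknown", "target": [{"code": "77176002", "display": "Smoker", "equivalence": "equivalent"}]},
        {"code": "unknown-if-ever", "target": [{"code": "266927001", "display": "Tobacco smoking consumption unknown", "equivalence": "equivalent"}]}
      ]
    }
  ]
}
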