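{
  "description": "Synthetic formulary for exercising the classification pipeline offline. Dose rules are mock simplifications for testing, not clinical guidance.",
  "entries": [
    {
      "canonical_name": "aspirin",
      "aliases": ["aspirin", "aspirin low dose", "apo-asa", "asaphen"],
      "strengths": ["81mg", "325mg", "500 MG"],
      "default_best": "B01",
      "default_next": "N02",
      "dose_rules": [
        {"max_mg": 100, "best": "B01", "next": null},
        {"min_mg": 325, "best": "N02", "next": "B01"}
      ]
    },
    {
      "canonical_name": "folic acid",
      "aliases": ["folic acid", "apo-folic", "jamp-folic acid"],
      "strengths": ["1.0 MG", "5.0 MG"],
      "default_best": "A11",
      "default_next": null,
      "dose_rules": [
        {"max_mg": 4.9, "best": "A11", "next": null},
        {"min_mg": 5, "best": "B03", "next": "A11"}
      ]
    },
    {
      "canonical_name": "prednisone",
      "aliases": ["prednisone", "apo-prednisone", "teva-prednisone"],
      "strengths": ["5.0 MG", "50 MG"],
      "default_best": "H02",
      "default_next": null,
      "dose_rules": [
        {"max_mg": 40, "best": "H02", "next": null},
        {"min_mg": 40.1, "best": "A07", "next": "H02"}
      ]
    },
    {
      "canonical_name": "metformin",
      "aliases": ["metformin", "apo-metformin", "glucophage"],
      "strengths": ["500MG", "850 MG"],
      "default_best": "A10",
      "default_next": null,
      "dose_rules": []
    },
    {
      "canonical_name": "quetiapine",
      "aliases": ["pms-quetiapine", "quetiapine", "teva-quetiapine"],
      "strengths": ["25 mg", "200 mg", "100.0 MG"],
      "default_best": "N05",
      "default_next": null,
      "dose_rules": []
    },
    {
      "canonical_name": "webber naturals womens 50 plus most",
      "aliases": ["webber naturals womens 50 plus most"],
      "strengths": ["UNK"],
      "default_best": "A11",
      "default_next": null,
      "dose_rules": []
    },
    {
      "canonical_name": "XYZ-1234",
      "aliases": ["xyz-1234"],
      "strengths": ["1 g"],
      "default_best": null,
      "default_next": null,
      "dose_rules": []
    },
    {
      "canonical_name": "carbamazepine",
      "aliases": ["carbamazepin tab", "carbamazepine", "tegretol"],
      "strengths": ["200MG", "400.0 MG"],
      "default_best": "N03",
      "default_next": null,
      "dose_rules": []
    },
    {
      "canonical_name": "entacapone",
      "aliases": ["teva-entacapone", "entacapone"],
      "strengths": ["200.0 MG"],
      "default_best": "N04",
      "default_next": null,
      "dose_rules": []
    },
    {
      "canonical_name": "midodrine",
      "aliases": ["apo-midodrine", "midodrine"],
      "strengths": ["2.5 MG", "5.0 MG"],
      "default_best": "C01",
      "default_next": null,
      "dose_rules": []
    },
    {
      "canonical_name": "hydroxyzine",
      "aliases": ["hydroxyzine hydrochloride", "atarax"],
      "strengths": ["10.0 MG", "25.0 MG"],
      "default_best": "N05",
      "default_next": "R06",
      "dose_rules": []
    },
    {
      "canonical_name": "domperidone",
      "aliases": ["apo-domperidone", "domperidone"],
      "strengths": ["10.0 MG"],
      "default_best": "A03",
      "default_next": null,
      "dose_rules": []
    },
    {
      "canonical_name": "nortriptyline",
      "aliases": ["aventyl", "nortriptyline"],
      "strengths": ["25.0 MG", "10.0 MG"],
      "default_best": "N06",
      "default_next": null,
      "dose_rules": []
    },
    {
      "canonical_name": "perindopril/indapamide",
      "aliases": ["sandoz perindopril erbumine/indapamide hd"],
      "strengths": ["0.0", "4/1.25 MG"],
      "default_best": "C09",
      "default_next": "C03",
      "dose_rules": []
    },
    {
      "canonical_name": "vitamin d2",
      "aliases": ["vitamin d2", "ergocalciferol"],
      "strengths": ["1.25 mg"],
      "default_best": "A11",
      "default_next": null,
      "dose_rules": []
    },
    {
      "canonical_name": "levothyroxine",
      "aliases": ["synthroid", "levothyroxine", "eltroxin"],
      "strengths": ["125.0 MCG", "50.0 MCG"],
      "default_best": "H03",
      "default_next": null,
      "dose_rules": []
    },
    {
      "canonical_name": "lamotrigine",
      "aliases": ["apo-lamotrigine", "lamotrigine"],
      "strengths": ["25.0 MG", "100.0 MG"],
      "default_best": "N03",
      "default_next": null,
      "dose_rules": []
    },
    {
      "canonical_name": "azithromycin",
      "aliases": ["jamp-azithromycin", "azithromycin"],
      "strengths": ["250.0 MG"],
      "default_best": "J01",
      "default_next": null,
      "dose_rules": []
    },
    {
      "canonical_name": "metoprolol",
      "aliases": ["metoprolol-l", "metoprolol", "apo-metoprolol"],
      "strengths": ["50.0 MG", "25.0 MG"],
      "default_best": "C07",
      "default_next": null,
      "dose_rules": []
    },
    {
      "canonical_name": "irbesartan",
      "aliases": ["sandoz irbesartan", "irbesartan"],
      "strengths": ["75.0 MG", "150.0 MG"],
      "default_best": "C09",
      "default_next": null,
      "dose_rules": []
    },
    {
      "canonical_name": "pregabalin",
      "aliases": ["apo-pregabalin", "pregabalin", "lyrica"],
      "strengths": ["75.0 MG", "150.0 MG", "25.0 MG"],
      "default_best": "N03",
      "default_next": "N06",
      "dose_rules": []
    },
    {
      "canonical_name": "ramipril",
      "aliases": ["apo-ramipril", "ramipril", "altace"],
      "strengths": ["10.0 MG", "5.0 MG", "2.5 MG"],
      "default_best": "C09",
      "default_next": null,
      "dose_rules": []
    },
    {
      "canonical_name": "bupropion",
      "aliases": ["odan bupropion sr", "bupropion", "wellbutrin"],
      "strengths": ["100.0 MG", "150.0 MG"],
      "default_best": "N06",
      "default_next": "N07",
      "dose_rules": []
    },
    {
      "canonical_name": "valacyclovir",
      "aliases": ["valacyclovir tab", "valacyclovir", "valtrex"],
      "strengths": ["500MG", "1000 MG"],
      "default_best": "J05",
      "default_next": null,
      "dose_rules": []
    },
    {
      "canonical_name": "olanzapine",
      "aliases": ["olanzapine", "zyprexa", "apo-olanzapine"],
      "strengths": ["10 MG", "5.0 MG", "2.5 MG"],
      "default_best": "N05",
      "default_next": null,
      "dose_rules": []
    },
    {
      "canonical_name": "rosuvastatin",
      "aliases": ["apo-rosuvastatin", "rosuvastatin", "crestor"],
      "strengths": ["10.0 MG", "20.0 MG", "5.0 MG"],
      "default_best": "C10",
      "default_next": null,
      "dose_rules": []
    },
    {
      "canonical_name": "carbidopa/levodopa",
      "aliases": ["carbidopa/levodopa er", "carbidopa/levodopa", "sinemet"],
      "strengths": ["25/100 MG", "50/200MG"],
      "default_best": "N04",
      "default_next": null,
      "dose_rules": []
    },
    {
      "canonical_name": "calcium + vitamin d",
      "aliases": ["calcium-ng-vitd - jam", "calcium magnesium zinc vitamin d3"],
      "strengths": ["UNK", "500/400 MG"],
      "default_best": "A12",
      "default_next": "A11",
      "dose_rules": []
    }
  ]
}
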