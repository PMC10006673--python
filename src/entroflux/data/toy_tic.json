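{
    "compartments": {
        "c": ""
    },
    "genes": [
        {
            "id": "g1",
            "name": ""
        },
        {
            "id": "g2",
            "name": ""
        },
        {
            "id": "g3",
            "name": ""
        },
        {
            "id": "g4",
            "name": ""
        }
    ],
    "id": "toy_tic",
    "metabolites": [
        {
            "compartment": "c",
            "id": "A",
            "name": ""
        },
        {
            "compartment": "c",
            "id": "B",
            "name": ""
        }
    ],
    "reactions": [
        {
            "gene_reaction_rule": "g1",
            "id": "v1",
            "lower_bound": 0.0,
            "metabolites": {
                "A": 1.0
            },
            "name": "",
            "subsystem": "Exchange",
            "upper_bound": 1000.0
        },
        {
            "gene_reaction_rule": "g2",
            "id": "v2",
            "lower_bound": 0.0,
            "metabolites": {
                "A": -1.0,
                "B": 1.0
            },
            "name": "",
            "subsystem": "Core",
            "upper_bound": 1000.0
        },
        {
            "gene_reaction_rule": "g3",
            "id": "v3",
            "lower_bound": 0.0,
            "metabolites": {
                "A": 1.0,
                "B": -1.0
            },
            "name": "",
            "subsystem": "Core",
            "upper_bound": 1000.0
        },
        {
            "gene_reaction_rule": "g4",
            "id": "v4",
            "lower_bound": 0.0,
            "metabolites": {
                "B": -1.0
            },
            "name": "",
            "subsystem": "Exchange",
            "upper_bound": 1000.0
        }
    ],
    "version": "1"
}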