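# Demo generator configuration: a small synthetic hospital (500 screened
# patients) exercising all five pipelines end to end.
n_patients: 500
seed: 7
year: 2022
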