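category,unit_cost,price_year
primary_care,64.07,2024
specialist,81.38,2024
pc_emergency,73.34,2024
hospital_emergency,215.06,2024
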