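id,year,irrigation_m3_ha,fert1_kg_ha,fert2_kg_ha,fert3_kg_ha
T1,2023,1525,562.5,562.5,562.5
T1,2024,1475,562.5,562.5,562.5
T2,2023,1525,750,750,750
T2,2024,1475,750,750,750
T3,2023,1525,937.5,937.5,937.5
T3,2024,1475,937.5,937.5,937.5
T4,2023,2287.5,562.5,750,937.5
T4,2024,2212.5,562.5,750,937.5
T5,2023,2287.5,750,937.5,562.5
T5,2024,2212.5,750,937.5,562.5
T6,2023,2287.5,937.5,562.5,750
T6,2024,2212.5,937.5,562.5,750
T7,2023,3050,562.5,937.5,750
T7,2024,2950,562.5,937.5,750
T8,2023,3050,750,562.5,937.5
T8,2024,2950,750,562.5,937.5
T9,2023,3050,937.5,750,562.5
T9,2024,2950,937.5,750,562.5
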