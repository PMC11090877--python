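# Dietary energy (kJ/cap/d) with shares, baseline vs minimum-deviation scenarios,
# average adult female, 16 main food categories + totals row.
main_category,baseline,baseline_share,health_only,health_only_share,ghge33,ghge33_share,ghge50,ghge50_share
Alcohol,129,0.02,122,0.02,118,0.02,84,0.01
Beverages,100,0.01,98,0.01,71,0.01,45,0.006
Cereals,1668,0.23,2052,0.28,2175,0.30,2660,0.36
Diet products,27,0.00,27,0.00,29,0.00,32,0.00
Eggs,135,0.02,157,0.02,173,0.02,146,0.02
Fats,1062,0.15,1098,0.15,1245,0.17,1116,0.15
Fish,174,0.02,243,0.03,223,0.03,208,0.03
Flavoring,22,0.00,22,0.00,22,0.00,23,0.00
Fruits,589,0.08,666,0.09,606,0.08,485,0.07
Ingredients,44,0.01,73,0.01,85,0.01,88,0.01
Legumes and nuts,292,0.04,360,0.05,413,0.06,456,0.06
Meat,746,0.10,540,0.07,347,0.05,90,0.01
Dairy,1359,0.19,869,0.12,839,0.11,804,0.11
Potatoes,260,0.036,310,0.04,337,0.05,474,0.06
Sugar,506,0.07,425,0.06,425,0.06,428,0.06
Vegetables,198,0.03,250,0.03,202,0.03,158,0.02
TOTAL,7311,1.00,7311,1.00,7311,1.00,7311,1.00
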