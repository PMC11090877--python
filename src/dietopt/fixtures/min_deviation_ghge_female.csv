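# Diet greenhouse-gas emissions (kg CO2e/cap/d) with shares, baseline vs
# minimum-deviation scenarios, average adult female, 16 main food categories + totals.
main_category,baseline,baseline_share,health_only,health_only_share,ghge33,ghge33_share,ghge50,ghge50_share
Alcohol,0.07,0.02,0.06,0.02,0.06,0.02,0.04,0.02
Beverages,0.21,0.05,0.20,0.06,0.12,0.05,0.04,0.02
Cereals,0.17,0.05,0.20,0.06,0.21,0.09,0.26,0.14
Diet products,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00
Eggs,0.07,0.02,0.08,0.02,0.09,0.03,0.07,0.04
Fats,0.24,0.06,0.18,0.05,0.21,0.08,0.18,0.10
Fish,0.12,0.03,0.17,0.05,0.15,0.06,0.14,0.08
Flavoring,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00
Fruits,0.25,0.07,0.28,0.09,0.25,0.10,0.19,0.10
Ingredients,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00
Legumes and nuts,0.04,0.01,0.05,0.01,0.05,0.02,0.05,0.03
Meat,1.35,0.36,0.95,0.30,0.52,0.21,0.25,0.13
Dairy,0.86,0.23,0.54,0.17,0.50,0.20,0.44,0.24
Potatoes,0.01,0.00,0.01,0.00,0.01,0.00,0.02,0.01
Sugar,0.10,0.03,0.08,0.03,0.09,0.03,0.09,0.05
Vegetables,0.30,0.08,0.39,0.12,0.26,0.10,0.12,0.06
TOTAL,3.78,1.00,3.20,1.00,2.52,1.00,1.89,1.00
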