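# Diet cost (EUR/cap/d) with shares, baseline vs minimum-deviation scenarios,
# average adult female, 16 main food categories + totals row.
main_category,baseline,baseline_share,health_only,health_only_share,ghge33,ghge33_share,ghge50,ghge50_share
Alcohol,0.38,0.07,0.36,0.07,0.35,0.07,0.25,0.06
Beverages,0.27,0.05,0.26,0.05,0.17,0.04,0.08,0.02
Cereals,0.23,0.04,0.27,0.05,0.28,0.06,0.32,0.08
Diet products,0.07,0.01,0.07,0.01,0.07,0.01,0.08,0.02
Eggs,0.08,0.01,0.09,0.02,0.10,0.02,0.09,0.02
Fats,0.20,0.04,0.20,0.04,0.23,0.05,0.21,0.05
Fish,0.36,0.07,0.49,0.09,0.45,0.09,0.42,0.11
Flavoring,0.03,0.01,0.03,0.01,0.03,0.01,0.03,0.01
Fruits,0.73,0.13,0.81,0.15,0.74,0.15,0.56,0.14
Ingredients,0.04,0.01,0.06,0.01,0.06,0.01,0.07,0.02
Legumes and nuts,0.17,0.03,0.20,0.04,0.23,0.05,0.26,0.06
Meat,0.81,0.15,0.59,0.11,0.34,0.07,0.11,0.03
Dairy,1.13,0.21,0.82,0.15,0.79,0.17,0.73,0.18
Potatoes,0.07,0.01,0.08,0.02,0.09,0.02,0.13,0.03
Sugar,0.27,0.05,0.21,0.04,0.23,0.05,0.25,0.06
Vegetables,0.62,0.11,0.80,0.15,0.63,0.13,0.43,0.11
TOTAL,5.45,1.00,5.34,1.00,4.78,1.00,4.00,1.00
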