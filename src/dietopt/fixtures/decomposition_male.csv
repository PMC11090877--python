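# Additive intra-/inter-category decomposition of changes in diet cost (EUR/cap/d)
# and GHGE (kg CO2e/cap/d) from baseline, average adult male, by scenario.
main_category,metric,scenario,intra,inter
Alcohol,cost,health_only,0.02,-0.16
Beverages,cost,health_only,-0.02,-0.01
Cereals,cost,health_only,0.00,0.15
Diet products,cost,health_only,0.00,0.00
Eggs,cost,health_only,0.00,-0.01
Fats,cost,health_only,-0.01,-0.03
Fish,cost,health_only,0.00,0.01
Flavoring,cost,health_only,0.00,0.00
Fruits,cost,health_only,-0.01,0.06
Ingredients,cost,health_only,0.01,0.00
Legumes and nuts,cost,health_only,0.00,0.04
Meat,cost,health_only,-0.04,-0.50
Dairy,cost,health_only,-0.11,-0.40
Potatoes,cost,health_only,0.00,0.01
Sugar,cost,health_only,0.00,-0.04
Vegetables,cost,health_only,-0.02,0.18
TOTAL,cost,health_only,-0.18,-0.69
Alcohol,cost,ghge33,0.02,-0.16
Beverages,cost,ghge33,-0.03,-0.02
Cereals,cost,ghge33,0.00,0.15
Diet products,cost,ghge33,0.00,0.00
Eggs,cost,ghge33,0.00,-0.01
Fats,cost,ghge33,-0.01,-0.02
Fish,cost,ghge33,0.00,0.00
Flavoring,cost,ghge33,0.00,0.00
Fruits,cost,ghge33,-0.01,0.05
Ingredients,cost,ghge33,0.01,0.00
Legumes and nuts,cost,ghge33,0.00,0.04
Meat,cost,ghge33,-0.08,-0.57
Dairy,cost,ghge33,-0.10,-0.40
Potatoes,cost,ghge33,0.00,0.01
Sugar,cost,ghge33,0.00,-0.03
Vegetables,cost,ghge33,-0.02,0.16
TOTAL,cost,ghge33,-0.23,-0.79
Alcohol,cost,ghge50,0.10,-0.41
Beverages,cost,ghge50,-0.09,-0.05
Cereals,cost,ghge50,-0.01,0.18
Diet products,cost,ghge50,0.00,0.00
Eggs,cost,ghge50,0.00,0.00
Fats,cost,ghge50,0.00,-0.01
Fish,cost,ghge50,0.01,-0.09
Flavoring,cost,ghge50,0.00,0.00
Fruits,cost,ghge50,-0.03,-0.03
Ingredients,cost,ghge50,0.00,0.00
Legumes and nuts,cost,ghge50,0.01,0.03
Meat,cost,ghge50,-0.19,-0.91
Dairy,cost,ghge50,-0.17,-0.31
Potatoes,cost,ghge50,0.00,0.03
Sugar,cost,ghge50,0.00,-0.01
Vegetables,cost,ghge50,-0.01,0.00
TOTAL,cost,ghge50,-0.39,-1.58
Alcohol,ghge,health_only,0.00,-0.04
Beverages,ghge,health_only,-0.01,-0.01
Cereals,ghge,health_only,-0.01,0.12
Diet products,ghge,health_only,0.00,0.00
Eggs,ghge,health_only,0.00,-0.01
Fats,ghge,health_only,-0.09,-0.02
Fish,ghge,health_only,0.00,0.00
Flavoring,ghge,health_only,0.00,0.00
Fruits,ghge,health_only,0.00,0.02
Ingredients,ghge,health_only,0.00,0.00
Legumes and nuts,ghge,health_only,0.00,0.01
Meat,ghge,health_only,-0.11,-0.81
Dairy,ghge,health_only,-0.28,-0.27
Potatoes,ghge,health_only,0.00,0.00
Sugar,ghge,health_only,0.00,-0.02
Vegetables,ghge,health_only,0.00,0.08
TOTAL,ghge,health_only,-0.51,-0.92
Alcohol,ghge,ghge33,0.00,-0.04
Beverages,ghge,ghge33,-0.02,-0.01
Cereals,ghge,ghge33,-0.01,0.13
Diet products,ghge,ghge33,0.00,0.00
Eggs,ghge,ghge33,0.00,0.00
Fats,ghge,ghge33,-0.08,-0.02
Fish,ghge,ghge33,0.00,0.00
Flavoring,ghge,ghge33,0.00,0.00
Fruits,ghge,ghge33,0.00,0.02
Ingredients,ghge,ghge33,0.00,0.00
Legumes and nuts,ghge,ghge33,0.00,0.01
Meat,ghge,ghge33,-0.41,-0.83
Dairy,ghge,ghge33,-0.28,-0.27
Potatoes,ghge,ghge33,0.00,0.00
Sugar,ghge,ghge33,0.00,-0.01
Vegetables,ghge,ghge33,-0.01,0.07
TOTAL,ghge,ghge33,-0.81,-0.96
Alcohol,ghge,ghge50,0.00,-0.09
Beverages,ghge,ghge50,-0.09,-0.03
Cereals,ghge,ghge50,-0.01,0.16
Diet products,ghge,ghge50,0.00,0.00
Eggs,ghge,ghge50,0.00,0.00
Fats,ghge,ghge50,-0.08,-0.01
Fish,ghge,ghge50,0.00,-0.03
Flavoring,ghge,ghge50,0.00,0.00
Fruits,ghge,ghge50,-0.01,-0.01
Ingredients,ghge,ghge50,0.00,0.00
Legumes and nuts,ghge,ghge50,0.00,0.01
Meat,ghge,ghge50,-0.56,-1.32
Dairy,ghge,ghge50,-0.34,-0.20
Potatoes,ghge,ghge50,0.00,0.00
Sugar,ghge,ghge50,0.00,-0.01
Vegetables,ghge,ghge50,-0.03,0.00
TOTAL,ghge,ghge50,-1.13,-1.51
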