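# Minimum-cost diet vs baseline, average adult male, 73 food categories + totals row.
# Per-food ghge_* cells were printed in kg CO2e/cap/d and are stored here in g (x1000);
# the TOTAL row is the printed totals row (already in g CO2e/cap/d).
food_id,name,main_category,qty_base_g,qty_mincost_g,ghge_base_g,ghge_mincost_g,cost_base_eur,cost_mincost_eur
beer_cider,Beer and cider,Alcohol,127.0,0.0,200,0,0.61,0.00
wine_spirit,Wine and spirit,Alcohol,19.2,0.0,0,0,0.23,0.00
coffee,Coffee,Beverages,495.0,0.0,200,0,0.22,0.00
soft_drink,Soft drink,Beverages,103.8,0.0,0,0,0.17,0.00
tea,Tea,Beverages,81.1,0.0,0,0,0.01,0.00
barley,Barley and barley products,Cereals,1.1,0.0,0,0,0.00,0.00
cereal_soy_drink,Cereal/seed/soy drinks,Cereals,7.7,0.0,0,0,0.03,0.00
other_grains,Other grains,Cereals,2.2,0.0,0,0,0.01,0.00
oat,Oat and oat products,Cereals,15.5,0.0,0,0,0.03,0.00
rice,Rice,Cereals,10.3,0.0,0,0,0.02,0.00
rye,Rye,Cereals,40.1,113.1,0,100,0.08,0.23
starches,Starches,Cereals,2.3,0.0,0,0,0.01,0.00
wheat,Wheat,Cereals,78.4,245.6,100,300,0.06,0.19
sport_foods,"Sport foods, nutritional support",Diet products,1.7,0.0,0,0,0.06,0.00
eggs,Eggs,Eggs,24.2,0.3,100,0,0.08,0.00
butter,Butter,Fats,4.9,0.0,100,0,0.02,0.00
blended_spread,Blended spread,Fats,13.6,0.0,100,0,0.08,0.00
cooking_animal_fat,Cooking and animal fat,Fats,5.1,0.0,0,0,0.02,0.00
oils,Oils,Fats,10.3,24.9,0,100,0.06,0.14
salad_dressings,Salad dressings,Fats,4.7,0.0,0,0,0.04,0.00
margarine_high,Margarines >= 55%,Fats,9.0,20.9,0,100,0.04,0.09
margarine_low,Margarines < 55%,Fats,5.1,0.0,0,0,0.02,0.00
fish_seafood,"Fish, seafood",Fish,25.4,19.3,100,100,0.27,0.20
fish_products,Fish products,Fish,10.3,0.0,0,0,0.18,0.00
condiments,Condiments,Flavoring,9.4,0.0,0,0,0.04,0.00
dried_spices,Dried spices and herbs,Flavoring,0.1,0.0,0,0,0.00,0.00
malaceous_fruit,Malaceous fruit,Fruits,32.0,0.0,0,0,0.06,0.00
berries,Berries,Fruits,24.2,0.0,0,0,0.09,0.00
citrus_fruit,Citrus fruit,Fruits,23.9,0.0,0,0,0.04,0.00
juice_drink,Juice drink,Fruits,75.8,0.0,100,0,0.32,0.00
canned_fruit,Canned fruit,Fruits,4.3,0.0,0,0,0.02,0.00
other_fruits,Other fruits,Fruits,50.7,0.0,100,0,0.12,0.00
juices,"Juices, including vegetable juices",Fruits,49.7,0.0,100,0,0.08,0.00
misc_ingredients,Miscellaneous ingredients,Ingredients,6.6,0.0,0,0,0.04,0.00
salt,Salt,Ingredients,4.2,1.5,0,0,0.01,0.00
sweeteners,Sweeteners,Ingredients,0.0,0.0,0,0,0.00,0.00
nuts_seeds,Nuts and seeds,Legumes and nuts,6.7,0.0,0,0,0.09,0.00
pulses,Pulse vegetables and products,Legumes and nuts,9.6,0.0,0,0,0.04,0.00
soya_products,Soya products,Legumes and nuts,2.7,0.0,0,0,0.01,0.00
beef_lamb,Beef and lamb/mutton,Meat,35.6,0.0,1100,0,0.37,0.00
cold_cuts_meat,"Cold cuts, meat products",Meat,24.1,0.0,400,0,0.26,0.00
offal,Offal,Meat,2.4,12.3,0,200,0.02,0.10
pork_game,Pork and game,Meat,40.9,0.0,300,0,0.34,0.00
poultry,Poultry,Meat,42.8,0.0,200,0,0.20,0.00
sausages,Sausages,Meat,28.1,0.0,200,0,0.17,0.00
cold_cuts_sausages,"Cold cuts, sausages",Meat,7.3,0.0,100,0,0.07,0.00
cheese_ripened_high,Ripened/processed cheese >17%,Dairy,26.9,0.0,400,0,0.24,0.00
cheese_ripened_low,Ripened/processed cheese <=17%,Dairy,6.5,0.0,100,0,0.06,0.00
cheese_fresh_high,Unripened/fresh cheese >15%,Dairy,4.1,0.0,0,0,0.04,0.00
cheese_fresh_low,Unripened/fresh cheese <=15%,Dairy,6.9,0.0,0,0,0.06,0.00
cream,Cream,Dairy,16.2,0.0,0,0,0.08,0.00
quark,Quark,Dairy,20.9,0.0,0,0,0.18,0.00
ice_cream,Ice cream,Dairy,9.8,0.0,0,0,0.05,0.00
skimmed_milk,Skimmed milk,Dairy,102.7,117.8,100,100,0.11,0.13
milk_high_fat,Milk with >2% fat,Dairy,25.4,405.0,0,400,0.02,0.34
milk_powders,Milk powders,Dairy,0.6,0.0,0,0,0.01,0.00
milk_low_fat,Milk with <=2% fat,Dairy,174.4,0.0,200,0,0.20,0.00
soured_milk,Soured/cultured milk,Dairy,29.5,0.0,0,0,0.05,0.00
fermented_other,"Fermented milk products, other",Dairy,3.7,0.0,0,0,0.02,0.00
yogurt,Yogurt,Dairy,50.5,0.0,100,0,0.12,0.00
potato_products,Potato products,Potatoes,12.9,0.0,0,0,0.05,0.00
potato,Potato,Potatoes,71.7,394.8,0,0,0.06,0.33
chocolate,Chocolate,Sugar,6.6,0.0,0,0,0.10,0.00
jam,Jam,Sugar,5.0,0.0,0,0,0.03,0.00
sugar_syrups,Sugar and syrups,Sugar,14.4,0.0,0,0,0.03,0.00
confectionery,Nonchocolate confectionery,Sugar,6.2,0.0,0,0,0.09,0.00
cabbage,Cabbage,Vegetables,13.6,59.2,0,0,0.03,0.14
edible_fungi,Edible fungi,Vegetables,3.6,0.0,0,0,0.02,0.00
root_vegetables,Root vegetables and tubers,Vegetables,28.3,0.0,0,0,0.06,0.00
canned_vegetables,Canned vegetables,Vegetables,19.0,0.0,0,0,0.08,0.00
fruit_vegetables,Fruit vegetables,Vegetables,75.8,0.0,200,0,0.20,0.00
leaf_vegetables,Leaf vegetables,Vegetables,21.6,0.0,0,0,0.17,0.00
onion_vegetables,Onion-family vegetables,Vegetables,14.7,0.0,0,0,0.02,0.00
TOTAL,All,All,2350.4,1414.8,5296.5,1452.1,6.90,1.88
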