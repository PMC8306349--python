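# Default 40 food-group names. Groups 1-36 are the network-analysis staples of
# US dietary-recall food grouping; the last four are generic placeholders a user
# is expected to replace with their own taxonomy's remaining categories.
milk
water
white_bread
whole_grain_bread
low_sugar_rte_cereals
high_sugar_rte_cereals
cooked_grains
pasta_based_dishes
quick_breads
cakes_cookies
sweets
salty_snacks
sugar_sweetened_beverages
coffee_tea
fruit_juice
fruits
green_vegetables
red_orange_vegetables
other_vegetables
potatoes
fried_potatoes
cheese
yogurt
eggs
meat
poultry
fish
cured_meat
protein_patties_loaves
nuts
legumes
soups
sandwiches
savory_pies
mayonnaise_salads
sauces
solid_fats
oils
condiments
other_beverages
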