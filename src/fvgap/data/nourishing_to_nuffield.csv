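category,domain,rung
food-based dietary guidelines,behaviour change communication,provide information
public awareness campaigns on healthy diets,behaviour change communication,provide information
nutrition counselling in primary care,behaviour change communication,enable choice
nutrition education and cooking skills in schools,behaviour change communication,enable choice
nutrition label standards,food environment,provide information
menu calorie labelling,food environment,provide information
incentives for store-owners to locate in underserved areas,food environment,enable choice
school fruit and vegetable scheme,food environment,guide choice by changing default
healthy food standards in public institutions,food environment,guide choice by changing default
fiscal policies to reduce the cost of fruits and vegetables,food environment,guide choice with incentives
health-related food taxes,food environment,guide choice with disincentives
restrict unhealthy food advertising to children,food environment,restrict choice
limit portion and package size,food environment,restrict choice
ban on industrial trans fats,food environment,eliminate choice
supply-chain incentives for fruit and vegetable production,food system,guide choice with incentives
public procurement of local produce,food system,enable choice
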