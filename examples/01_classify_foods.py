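"""Classify individual foods against the 'high in' symbol thresholds.

A packaged food displays a 'high in' symbol for sodium, total sugars or
saturated fat when the amount in its evaluation basis (reference amount,
stated serving, or 50 g for small-RA foods) meets or exceeds 15% of the
daily value (30% for main dishes with RA >= 200 g).
"""

from fopl_impact import ThresholdPolicy, classify

policy = ThresholdPolicy()

foods = {
    "canned soup (main dish, RA 250 g)": {
        "food_id": "soup", "reference_amount_g": 250.0,
        "sodium_mg": 690.0, "sugars_g": 2.0, "satfat_g": 0.5,
    },
    "chocolate bar (small RA 20 g, per 50 g basis)": {
        "food_id": "bar", "reference_amount_g": 20.0,
        "sodium_mg": 80.0, "sugars_g": 52.0, "satfat_g": 12.0,
    },
    "plain yogurt (RA 125 g)": {
        "food_id": "yogurt", "reference_amount_g": 125.0,
        "sodium_mg": 50.0, "sugars_g": 6.0, "satfat_g": 2.0,
    },
}

for name, food in foods.items():
    p = classify(food, policy)
    flags = [n for n, f in [("sodium", p.high_sodium), ("sugars", p.high_sugars),
                            ("satfat", p.high_satfat)] if f]
    print(f"{name}: {p.count} symbol(s) {flags or ''}")

# The soup carries 1725 mg sodium per 250 g = 75% DV, far above the 30%
# main-dish threshold; the bar exceeds the sugars and saturated-fat
# thresholds on its 50 g basis; the yogurt is below every threshold.
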