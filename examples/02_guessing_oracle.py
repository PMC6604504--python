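"""Exact pass probabilities for a respondent who only guesses.

On a homogeneous bank of four-option items the 3-of-5 county rule admits a
guesser with probability 0.103515625 (binomial closed form); the heroin
quiz's either/or rule over two four-option items admits 1 - 0.75^2 =
0.4375.  The shipped banks mix yes/no items in, so their guessing rate is
higher -- the oracle composes the exact Poisson-binomial tail over all 252
possible draws.
"""
from quizscreen import (build_drug_quiz, county_pass_probability, default_config,
                        drug_pass_probability, item_success_profile)

config = default_config()
print("homogeneous 4-option bank:", county_pass_probability([0.25] * 10))
profile = item_success_profile(config.banks["ashford"])  # structural guessing
print("shipped ashford bank     :", round(county_pass_probability(profile), 6))
quiz = build_drug_quiz(config.catalog, "heroin")
print("heroin quiz guesser      :", drug_pass_probability(quiz, {"cap_size": 0.25, "price": 0.25}))
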