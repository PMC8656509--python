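"""Value the packaged Guizhou survey years and account for the change.

Each land-use category's area (hm2) is multiplied by its per-hectare
service coefficient (CNY/hm2/yr); the account reports values in billion
CNY, shares of the yearly total, and the between-survey change.
"""

import esvgrey as eg

fx = eg.make_study_fixture()
account = eg.compute_esv(fx.areas, fx.vc)

print(account.report().to_string())
print()
total_2009 = account.totals[2009] / 1e9
total_2018 = account.totals[2018] / 1e9
print(
    f"Total ESV fell from {total_2009:.2f} to {total_2018:.2f} billion CNY "
    f"({eg.change_rate(total_2009, total_2018):+.3f}%): the decline is driven "
    "almost entirely by forest-land loss, the category with ~78% of the value."
)
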