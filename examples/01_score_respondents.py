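"""Score individual respondents on the 0-10 composite endpoint.

Builds three records by hand — a best-possible state, a respondent with six
functional limitations of whom three items went unanswered (pro-rated), and
one with too many missing morbidity items to be scoreable — and prints the
resulting component and index scores.
"""

import numpy as np
import pandas as pd

from topicscep import CodingScheme, score_cep
from topicscep.scoring import FUNCTIONAL_COLS, ITEM_COLS, MORBIDITY_COLS

scheme = CodingScheme.default()

def fresh_best_row():
    return {
        c: scheme.items[c].native_max if scheme.items[c].higher_is_better
        else scheme.items[c].native_min
        for c in ITEM_COLS
    }

rows = [fresh_best_row(), fresh_best_row(), fresh_best_row()]
# respondent 1: six functional limitations, three functional items unanswered
for c in FUNCTIONAL_COLS[:6]:
    rows[1][c] = 1
for c in FUNCTIONAL_COLS[12:]:
    rows[1][c] = np.nan
# respondent 2: five morbidity items unanswered -> exceeds the <5 tolerance
for c in MORBIDITY_COLS[:5]:
    rows[2][c] = np.nan

result = score_cep(pd.DataFrame(rows), scheme)
print(result[["functional_limitations", "raw_cep", "indexed_cep", "scoreable"]].round(3))
print()
print(
    "Respondent 0 is at the best state in every domain and scores the index\n"
    "maximum of 10. Respondent 1's functional component was pro-rated to\n"
    f"{result.loc[1, 'functional_limitations']:.1f} points ((6/12) x 15), costing"
    f" 0.12 points per limitation on the raw\nscale (raw "
    f"{result.loc[1, 'raw_cep']:.2f}). Respondent 2 exceeded the missing-item"
    " tolerance and\nreceives no score at all (scoreable=False)."
)
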