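"""Score generated reports: BLEU-1..4, ROUGE-L, CIDEr and clinical efficacy.

Clinical efficacy compares the pathology terms extracted from generated
vs reference reports, micro-averaged over every (sample, label) pair.
"""

import xraycap as xc

references = [
    ["opacityleft . left lung opacity . there is a focal opacity in the left lung ."],
    ["none . no acute findings . the lungs are clear and the cardiac silhouette is normal ."],
    ["enlargedheart . cardiomegaly . the cardiac silhouette is enlarged ."],
]
generated = [
    "opacityleft . left lung opacity . a patchy opacity is seen in the left lung .",
    "none . no acute findings . the lungs are clear and the cardiac silhouette is normal .",
    "none . no acute findings . the lungs are clear .",
]

labels = [xc.phantom.label_token(k)
          for k in xc.phantom.PATHOLOGY_KINDS if k != "none"]
report = xc.evaluate_all(generated, references, labels)

d = report.as_dict()
for i, b in enumerate(d["bleu"], 1):
    print(f"BLEU-{i}   : {b:.4f}")
print(f"ROUGE-L  : {d['rouge_l']:.4f}")
print(f"CIDEr    : {d['cider']:.4f}   (0..10; consensus TF-IDF n-grams)")
print(f"gm-BLEU  : {d['gm_bleu']:.4f}   (model-selection criterion)")
print("CE       :", {k: round(v, 3) for k, v in d["ce"].items()
                     if k in ("accuracy", "precision", "recall", "f1")})
# The second report matches exactly (all metrics reward it); the third
# misses the cardiomegaly mention, which shows up as a CE false negative.
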