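# COVID-19 EUA drug catalogue: canonical labels, active ingredients and
# common synonyms. Entries with two or more ingredients are combination
# therapies and normalise to a single canonical label.
drugs:
  - label: Nirmatrelvir/Ritonavir
    ingredients: [nirmatrelvir, ritonavir]
    synonyms: [paxlovid]
  - label: Casirivimab/Imdevimab
    ingredients: [casirivimab, imdevimab]
    synonyms: [regen-cov]
  - label: Remdesivir
    ingredients: [remdesivir]
    synonyms: [veklury]
  - label: Bamlanivimab
    ingredients: [bamlanivimab]
  - label: Bamlanivimab/Etesevimab
    ingredients: [bamlanivimab, etesevimab]
  - label: Sotrovimab
    ingredients: [sotrovimab]
    synonyms: [xevudy]
  - label: Baricitinib
    ingredients: [baricitinib]
    synonyms: [olumiant]
  - label: Bebtelovimab
    ingredients: [bebtelovimab]
  - label: Cilgavimab/Tixagevimab
    ingredients: [cilgavimab, tixagevimab]
    synonyms: [evusheld]
  - label: Tocilizumab
    ingredients: [tocilizumab]
    synonyms: [actemra]
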