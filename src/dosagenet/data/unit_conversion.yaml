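# Historical Chinese mass units by dynasty.
# fen_per_unit: how many Fen one unit contains (1 Liang = 10 Qian = 100 Fen).
# grams_per_fen: metric value of one Fen in each dynasty.
version: 1
fen_per_unit:
  Fen: 1
  Qian: 10
  Liang: 100
grams_per_fen:
  SongYuan: 0.4
  MingQing: 0.37
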