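# Normal-description templates for the four thoracic anatomical regions of a
# Vietnamese CXR radiology report.  A region is normal iff one of its
# templates appears verbatim (after normalization) in the report DESCRIPTION.
# The strings are shipped as published, including apparent typographical
# variants ("khôg thâ`y", "xoung"); templates are data — a site can drop in a
# corrected file without code changes.
chest_wall:
  - "không thâ`y hình bâ`t thuòng xoung lô´ng nguc"
  - "không thâ`y hình tôn thuòng xuong lô´ng nguc"
pleura:
  - "không thâ`y hình tràn dich màng phôi"
  - "không thâ`y hình tràn dich, khí màng phôi"
  - "khôg thâ`y hình tràn khí, tràn dich màng phôi"
lung:
  - "nhu mô phôi không thâ`y bâ`t thuòng"
mediastinum:
  - "hình tim vâ` trung thâ`t không thâ`y bâ`t thuòng"
  - "hình tim vâ` trung thâ`t bình thuòng"
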