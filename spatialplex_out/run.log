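2026-09-06 02:06:17,834 spatialplex ERROR configuration error: cell_table mode requires cell_table_path
2026-09-06 02:07:26,992 spatialplex ERROR configuration error: cell_table mode requires cell_table_path
2026-09-06 02:12:33,347 spatialplex ERROR configuration error: cell_table mode requires cell_table_path
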