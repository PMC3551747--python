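{
  "ribospecies_by_date": {
    "description": "Symbiont ribospecies by sampling date (N=153 worms)",
    "row_axis": "date",
    "col_axis": "ribospecies",
    "row_labels": ["Oct-06", "Jan-07", "Aug-07", "Dec-07", "Mar-09"],
    "col_labels": ["Rs1", "Rs2"],
    "observed": [[31, 1], [18, 1], [35, 0], [32, 2], [13, 20]],
    "printed_expected": [[27.0, 5.0], [16.0, 3.0], [29.5, 5.5], [28.7, 5.3], [27.8, 5.2]],
    "printed_G": 56.736,
    "printed_df": 5,
    "printed_df_note": "printed df=5 is inconsistent with the 5x2 layout; (r-1)(c-1)=4",
    "printed_P": "<0.0001"
  },
  "ribospecies_by_bone": {
    "description": "Symbiont ribospecies by bone substrate",
    "row_axis": "bone",
    "col_axis": "ribospecies",
    "row_labels": ["whale", "cow"],
    "col_labels": ["Rs1", "Rs2"],
    "observed": [[94, 17], [35, 7]],
    "printed_expected": [[93.6, 17.4], [35.4, 6.6]],
    "printed_G": 0.042,
    "printed_df": 1,
    "printed_P": "0.838"
  },
  "host_by_date": {
    "description": "Host species by sampling date (rare species lumped into 'other')",
    "row_axis": "date",
    "col_axis": "host_species",
    "row_labels": ["Oct-06", "Jan-07", "Aug-07", "Dec-07", "Mar-09"],
    "col_labels": ["O. rubiplumus", "O. frankpressi", "green-palp", "nude-palp A", "other"],
    "observed": [
      [22, 1, 1, 0, 8],
      [19, 0, 0, 0, 0],
      [10, 14, 0, 2, 9],
      [9, 0, 12, 10, 3],
      [7, 19, 0, 0, 7]
    ],
    "printed_expected": [
      [14.0, 7.1, 2.7, 2.5, 5.6],
      [8.3, 4.2, 1.6, 1.5, 3.4],
      [15.3, 7.8, 3.0, 2.7, 6.2],
      [14.9, 7.6, 2.9, 2.7, 6.0],
      [14.5, 7.3, 2.8, 2.6, 5.8]
    ],
    "printed_G": 140.298,
    "printed_df": 16,
    "printed_P": "<0.0001"
  },
  "host_by_ribospecies": {
    "description": "Host species by symbiont ribospecies; the printed Rs1/Rs2 row labels (totals 24 and 129) are swapped relative to the ribospecies_by_date totals (Rs1=129, Rs2=24); counts preserved as printed",
    "row_axis": "ribospecies",
    "col_axis": "host_species",
    "row_labels": ["Rs1", "Rs2"],
    "col_labels": ["O. rubiplumus", "O. frankpressi", "green-palp", "nude-palp A", "other"],
    "observed": [[8, 7, 2, 1, 6], [59, 27, 11, 11, 21]],
    "printed_expected": [[10.5, 5.3, 2.0, 1.9, 4.2], [56.5, 28.7, 11.0, 10.1, 22.8]],
    "printed_G": 2.702,
    "printed_df": 4,
    "printed_P": "<0.6088"
  },
  "host_by_bone": {
    "description": "Host species by bone substrate",
    "row_axis": "bone",
    "col_axis": "host_species",
    "row_labels": ["whale", "cow"],
    "col_labels": ["O. rubiplumus", "O. frankpressi", "green-palp", "nude-palp A", "other"],
    "observed": [[63, 32, 0, 10, 6], [4, 2, 13, 2, 21]],
    "printed_expected": [[48.6, 24.7, 9.4, 8.7, 19.6], [18.4, 9.3, 3.6, 3.3, 7.4]],
    "printed_G": 94.900,
    "printed_df": 4,
    "printed_P": "<0.0001"
  }
}
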