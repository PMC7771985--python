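analysis	modality	interval	start_age	stop_age
adherence_grid	mt-sDNA	2	45	75
adherence_grid	mt-sDNA	2	45	80
adherence_grid	mt-sDNA	2	45	85
adherence_grid	mt-sDNA	2	50	75
adherence_grid	mt-sDNA	2	50	80
adherence_grid	mt-sDNA	2	50	85
adherence_grid	mt-sDNA	2	55	75
adherence_grid	mt-sDNA	2	55	80
adherence_grid	mt-sDNA	2	55	85
adherence_grid	mt-sDNA	3	45	75
adherence_grid	mt-sDNA	3	45	80
adherence_grid	mt-sDNA	3	45	85
adherence_grid	mt-sDNA	3	50	75
adherence_grid	mt-sDNA	3	50	80
adherence_grid	mt-sDNA	3	50	85
adherence_grid	mt-sDNA	3	55	75
adherence_grid	mt-sDNA	3	55	80
adherence_grid	mt-sDNA	3	55	85
adherence_grid	FIT	1	45	75
adherence_grid	FIT	1	45	80
adherence_grid	FIT	1	45	85
adherence_grid	FIT	1	50	75
adherence_grid	FIT	1	50	80
adherence_grid	FIT	1	50	85
adherence_grid	FIT	1	55	75
adherence_grid	FIT	1	55	80
adherence_grid	FIT	1	55	85
adherence_grid	FIT	2	45	75
adherence_grid	FIT	2	45	80
adherence_grid	FIT	2	45	85
adherence_grid	FIT	2	50	75
adherence_grid	FIT	2	50	80
adherence_grid	FIT	2	50	85
adherence_grid	FIT	2	55	75
adherence_grid	FIT	2	55	80
adherence_grid	FIT	2	55	85
adherence_grid	HSgFOBT	1	45	75
adherence_grid	HSgFOBT	1	45	80
adherence_grid	HSgFOBT	1	45	85
adherence_grid	HSgFOBT	1	50	75
adherence_grid	HSgFOBT	1	50	80
adherence_grid	HSgFOBT	1	50	85
adherence_grid	HSgFOBT	1	55	75
adherence_grid	HSgFOBT	1	55	80
adherence_grid	HSgFOBT	1	55	85
adherence_grid	HSgFOBT	2	45	75
adherence_grid	HSgFOBT	2	45	80
adherence_grid	HSgFOBT	2	45	85
adherence_grid	HSgFOBT	2	50	75
adherence_grid	HSgFOBT	2	50	80
adherence_grid	HSgFOBT	2	50	85
adherence_grid	HSgFOBT	2	55	75
adherence_grid	HSgFOBT	2	55	80
adherence_grid	HSgFOBT	2	55	85
differential_base_case	mt-sDNA	2	45	75
differential_base_case	mt-sDNA	2	45	80
differential_base_case	mt-sDNA	2	50	75
differential_base_case	mt-sDNA	2	50	80
differential_base_case	mt-sDNA	3	45	75
differential_base_case	mt-sDNA	3	45	80
differential_base_case	mt-sDNA	3	50	75
differential_base_case	mt-sDNA	3	50	80
differential_base_case	FIT	1	45	75
differential_base_case	FIT	1	45	80
differential_base_case	FIT	1	50	75
differential_base_case	FIT	1	50	80
differential_base_case	FIT	2	45	75
differential_base_case	FIT	2	45	80
differential_base_case	FIT	2	50	75
differential_base_case	FIT	2	50	80
differential_base_case	HSgFOBT	1	45	75
differential_base_case	HSgFOBT	1	45	80
differential_base_case	HSgFOBT	1	50	75
differential_base_case	HSgFOBT	1	50	80
differential_base_case	HSgFOBT	2	45	75
differential_base_case	HSgFOBT	2	45	80
differential_base_case	HSgFOBT	2	50	75
differential_base_case	HSgFOBT	2	50	80
assigned_counts	mt-sDNA	3	45	75
assigned_counts	mt-sDNA	3	50	75
assigned_counts	FIT	1	45	75
assigned_counts	FIT	1	50	75
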