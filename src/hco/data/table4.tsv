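subject_id	gyri_left_hemisphere	gyri_right_hemisphere	other_brain_regions
Subject01	Anterior part of left middle frontal gyrus, Caudal part of left anterior cingulate gyrus, Cortex of left insula, Left frontal pole, Left lateral orbital gyrus, Left medial orbital gyrus, Left posterior cingulate gyrus, Left precentral gyrus, Left superior frontal gyrus, Opercular part of left inferior frontal gyrus, Triangular part of left inferior frontal gyrus	Anterior part of right middle frontal gyrus, Caudal part of right anterior cingulate gyrus, Cortex of right insula, Isthmus of right cingulate gyrus, Opercular part of right inferior frontal gyrus, Orbital part of right inferior frontal gyrus, Right frontal pole, Right inferior temporal gyrus, Right lateral occipital gyrus, Right lingual gyrus, Right medial orbital gyrus, Right middle temporal gyrus, Right posterior cingulate gyrus, Right precuneus, Right superior frontal gyrus, Right superior parietal lobule, Rostral part of right anterior cingulate gyrus, Triangular part of right inferior frontal gyrus	Brainstem, Left globus pallidus, Left putamen, Left thalamus, Right globus pallidus, Right putamen, Right thalamus
Subject02	Anterior part of left middle frontal gyrus, Caudal part of left anterior cingulate gyrus, Left medial orbital gyrus, Left middle temporal gyrus, Left paracentral lobule, Left posterior cingulate gyrus, Left precentral gyrus, Left precuneus, Left superior frontal gyrus, Opercular part of left inferior frontal gyrus, Posterior part of left middle frontal gyrus, Rostral part of left anterior cingulate gyrus	Anterior part of right middle frontal gyrus, Caudal part of right anterior cingulate gyrus, Cortex of right insula, Isthmus of right cingulate gyrus, Opercular part of right inferior frontal gyrus, Right frontal pole, Right inferior temporal gyrus, Right middle temporal gyrus, Right paracentral lobule, Right posterior cingulate gyrus, Right precuneus, Right superior frontal gyrus	Brainstem, Left globus pallidus, Left putamen, Left thalamus, Right globus pallidus, Right putamen, Right thalamus
Subject03	Anterior part of left middle frontal gyrus, Left frontal pole, Left inferior parietal lobule, Left inferior temporal gyrus, Left medial orbital gyrus, Left middle temporal gyrus, Left posterior cingulate gyrus, Left superior frontal gyrus, Left supramarginal gyrus, Posterior part of left middle frontal gyrus	Anterior part of right middle frontal gyrus, Caudal part of right anterior cingulate gyrus, Isthmus of right cingulate gyrus, Opercular part of right inferior frontal gyrus, Orbital part of right inferior frontal gyrus, Right inferior parietal lobule, Right inferior temporal gyrus, Right lateral occipital gyrus, Right middle temporal gyrus, Right paracentral lobule, Right posterior cingulate gyrus, Right precentral gyrus, Right precuneus, Right superior frontal gyrus, Right supramarginal gyrus, Rostral part of right anterior cingulate gyrus, Triangular part of right inferior frontal gyrus	Brainstem, Left putamen, Left thalamus, Right caudate nucleus, Right globus pallidus, Right putamen, Right thalamus
Subject04	Anterior part of left middle frontal gyrus, Caudal part of left anterior cingulate gyrus, Cortex of left insula, Left frontal pole, Left inferior parietal lobule, Left inferior temporal gyrus, Left lateral occipital gyrus, Left medial orbital gyrus, Left postcentral gyrus, Left posterior cingulate gyrus, Left precentral gyrus, Left superior frontal gyrus, Left superior parietal lobule, Left superior temporal gyrus, Left supramarginal gyrus, Opercular part of left inferior frontal gyrus, Orbital part of left inferior frontal gyrus, Triangular part of left inferior frontal gyrus	Anterior part of right middle frontal gyrus, Caudal part of right anterior cingulate gyrus, Cortex of right insula, Orbital part of right inferior frontal gyrus, Right frontal pole, Right inferior parietal lobule, Right lateral occipital gyrus, Right lingual gyrus, Right medial orbital gyrus, Right paracentral lobule, Right postcentral, Right posterior cingulate gyrus, Right precentral gyrus, Right precuneus, Right superior frontal gyrus, Right supramarginal gyrus, Triangular part of right inferior frontal gyrus	Brainstem, Left globus pallidus, Left putamen, Left thalamus, Right caudate nucleus, Right globus pallidus, Right putamen, Right thalamus
Subject05	Anterior part of left middle frontal gyrus, Caudal part of left anterior cingulate gyrus, Cortex of left insula, Left frontal pole, Left fusiform gyrus, Left inferior temporal gyrus, Left lateral orbital gyrus, Left medial orbital gyrus, Left paracentral lobule, Left posterior cingulate, Left precentral gyrus, Left superior frontal gyrus, Posterior part of left middle frontal gyrus, Triangular part of left inferior frontal gyrus	Anterior part of right middle frontal gyrus, Caudal part of right anterior cingulate gyrus, Right frontal pole, Right inferior parietal lobule, Right inferior temporal gyrus, Right lateral occipital gyrus, Right lateral orbital gyrus, Right lingual gyrus, Right medial orbital gyrus, Right middle temporal gyrus, Right paracentral lobule, Right posterior cingulate gyrus, Right precentral gyrus, Right precuneus, Right superior frontal gyrus, Right supramarginal gyrus, Rostral part of right anterior cingulate gyrus	Brainstem, Left caudate nucleus, Left putamen, Left thalamus, Right caudate nucleus, Right globus pallidus, Right putamen, Right thalamus
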